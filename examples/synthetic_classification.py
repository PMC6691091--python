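"""Full unsupervised pipeline on a synthetic multi-class dataset.

Generates MNIST-like sparse patterns, greedy-trains a single-layer spiking
network for one epoch, labels the output neurons by firing-time confidence
and evaluates held-out accuracy.  Also reports the per-synapse update
counts that make greedy training endurance-friendly.
"""

from memstdp import SyntheticSpec, VariationSpec, generate_synthetic
from memstdp.experiments import train_and_evaluate

spec = SyntheticSpec(image_side=12, n_classes=4, samples_per_class=150, seed=5)
images, labels = generate_synthetic(spec)
n_train = 480
xtr, ytr = images[:n_train], labels[:n_train]
xte, yte = images[n_train:], labels[n_train:]
print(f"{n_train} training / {len(xte)} test images, "
      f"{spec.n_classes} classes, {spec.image_side ** 2} input neurons\n")

acc, record = train_and_evaluate(xtr, ytr, xte, yte, n_outputs=8,
                                 variation=VariationSpec(), seed=2)
print(f"test accuracy after one unsupervised epoch: {acc:.1%}")
print(f"mean pattern-phase length: {record.mean_pattern_steps:.1f} steps "
      "(greedy stops at the first output spike)")
print(f"mean update operations per image: "
      f"{record.mean_updates_per_image:.1f} "
      "(each a single programming pulse pair on one device)")
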