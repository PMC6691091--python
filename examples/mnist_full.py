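"""Full-scale MNIST reproduction (requires locally downloaded IDX files).

Run as:
    python examples/mnist_full.py /path/to/mnist_dir [n_train] [n_test]

where the directory holds the standard uncompressed IDX files
(train-images-idx3-ubyte, train-labels-idx1-ubyte, t10k-images-idx3-ubyte,
t10k-labels-idx1-ubyte).  At full scale (784x50 network, 60 000 training
images, one epoch) expect roughly 75-79% test accuracy, a mean pattern
phase of ~160 steps and a maximum per-synapse update count below 200; the
run takes tens of minutes on one CPU.  No download is attempted here.
"""

import sys
from pathlib import Path

from memstdp import (
    LifConfig, LifLayerState, StdpParams, VariationSpec, greedy_train_epoch,
    read_idx_images, read_idx_labels, sample_d2d,
)
from memstdp.inference import evaluate_accuracy, label_neurons

if len(sys.argv) < 2:
    sys.exit("usage: python examples/mnist_full.py /path/to/mnist_dir "
             "[n_train] [n_test]")
root = Path(sys.argv[1])
n_train = int(sys.argv[2]) if len(sys.argv) > 2 else 60_000
n_test = int(sys.argv[3]) if len(sys.argv) > 3 else 10_000

xtr = read_idx_images(root / "train-images-idx3-ubyte")[:n_train]
ytr = read_idx_labels(root / "train-labels-idx1-ubyte")[:n_train]
xte = read_idx_images(root / "t10k-images-idx3-ubyte")[:n_test]
yte = read_idx_labels(root / "t10k-labels-idx1-ubyte")[:n_test]
print(f"loaded {len(xtr)} training / {len(xte)} test images")

seed = 0
syn = sample_d2d(StdpParams(), VariationSpec(), 784, 50, seed)
state = LifLayerState.create(50, LifConfig())
record = greedy_train_epoch(xtr, syn, state, seed=seed, progress_every=1000)
print(f"training done: {record.total_steps} total steps, "
      f"mean pattern phase {record.mean_pattern_steps:.1f} steps, "
      f"max per-synapse update count {syn.update_counts.max()}")

table = label_neurons(syn.weights, state.thresholds, xtr, ytr, seed=seed)
acc = evaluate_accuracy(xte, yte, syn.weights, state.thresholds, table,
                        seed=seed)
print(f"test accuracy: {acc:.1%}")

try:
    from memstdp.plotting import weight_map_grid
    weight_map_grid(syn.weights, 28, path="weight_maps.png")
    print("wrote weight_maps.png (per-neuron receptive fields)")
except Exception as exc:  # plotting is best-effort
    print(f"skipped weight-map export: {exc}")
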