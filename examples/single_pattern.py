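"""Greedy vs conventional training on one noise-free binary pattern.

A single output neuron learns a sparse 10x10 pattern at the full device
learning rate (A+ = 1.0).  Greedy training drives both the pattern-pixel
and background-pixel error rates to zero; the conventional fixed-duration
baseline keeps re-depressing learned pattern pixels and converges worse.
"""

from memstdp import (
    LifConfig, LifLayerState, StdpParams, SyntheticSpec, TrainConfig,
    VariationSpec, conventional_train_epoch, generate_synthetic,
    greedy_train_epoch, pixel_error_rates, sample_d2d,
)

spec = SyntheticSpec(image_side=10, n_classes=1, pattern_pixel_fraction=0.15,
                     background_intensity=0, pixel_noise_sd=0.0,
                     samples_per_class=50, seed=3, shuffle=False)
images, _ = generate_synthetic(spec)
target = images[0]
print(f"pattern: {int((target > 0).sum())} bright pixels on a "
      f"{spec.image_side}x{spec.image_side} dark background, "
      f"{len(images)} presentations\n")

for name, train_fn, cfg in [
    ("greedy", greedy_train_epoch, TrainConfig()),
    ("conventional", conventional_train_epoch, TrainConfig(mode="conventional")),
]:
    syn = sample_d2d(StdpParams(), VariationSpec(), 100, 1, seed=7)
    state = LifLayerState.create(1, LifConfig())
    rec = train_fn(images, syn, state, train=cfg, seed=11)
    pe, be = pixel_error_rates(syn.weights[:, 0], target)
    print(f"{name:>13}: pattern error {pe:.2f}, background error {be:.2f}, "
          f"{rec.mean_updates_per_image:.0f} updates/image "
          f"(error = fraction of pixels whose synapse sits on the wrong "
          f"side of the conductance midpoint)")
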