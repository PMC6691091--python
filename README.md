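# memstdp

Simulation of **unsupervised spiking neural networks trained on memristive
(1T1R RRAM) synapse arrays**, for researchers studying how in-memory
neuromorphic hardware can learn despite coarse, noisy, failure-prone
devices.

Real analog RRAM devices switch abruptly: a single programming pulse can
move the conductance by tens of percent of the dynamic range, while
textbook STDP learning rules assume learning rates of 10⁻⁴–10⁻². This
package implements the *greedy pattern/background* training scheme that
closes that gap, together with the device physics abstractions it runs on:

- **Soft-bound STDP synapse model.** For a pre/post spike pair with lag
  Δt = t_post − t_pre,

  ```
  ΔW =  A₊ (W_max − W) exp(−Δt/τ₊)      Δt > 0
  ΔW = −A₋ (W − W_min) exp(−|Δt|/τ₋)    Δt < 0
  ```

  with device-fitted defaults A₊ = 1.0, A₋ = 0.6, τ₊ = τ₋ = 150 ns,
  W ∈ [10, 50] μS (on/off ratio 5). Update magnitudes shrink near the
  bounds, matching measured RRAM switching.
- **1T1R waveform analysis.** Piecewise-linear bit-line/source-line/gate
  pulses; the cell voltage V_CELL = V_BL − V_SL is classified as SET,
  RESET or no-op per overlap lag (peaks 1.6 V SET / 2.3 V RESET at the
  default shapes; isolated pulses never switch).
- **Poisson rate coding with two phases.** Images normalized by total
  intensity drive Bernoulli-per-50 ns-step spike trains; the original image
  runs until the first output spike (*pattern phase*, factor f_pattern = 1),
  then its 255 − I complement runs for 10 steps (*background phase*,
  factor f_background = 7) to depress irrelevant synapses.
- **LIF output layer** with winner-take-all lateral inhibition (one spike
  per step, global reset) and homeostatic threshold adaptation
  θ += 0.1·(A − T) per image over a 1000-image window.
- **Greedy training**: exactly one post spike per stimulus, potentiation
  only in the pattern phase, depression only in the background phase, a
  4-step STDP window — tens of device updates per image instead of ~10⁴.
- **Device non-idealities**: Gaussian device-to-device and cycle-to-cycle
  parameter variation (untruncated — negative amplitudes model programming
  disorder), stuck devices from swapped bounds or an explicit failure
  rate, per-synapse update counting for endurance accounting.

## Worked example

```bash
python examples/single_pattern.py
```

```
pattern: 15 bright pixels on a 10x10 dark background, 50 presentations

       greedy: pattern error 0.00, background error 0.00, 31 updates/image ...
 conventional: pattern error 0.07, background error 0.00, 239 updates/image ...
```

A single output neuron learns a sparse binary pattern at the full device
learning rate. After 50 presentations every pattern-pixel synapse sits
above the conductance midpoint and every background-pixel synapse below it
(both error rates 0.00) under greedy training, using ~31 device updates
per image; the conventional fixed-duration baseline keeps re-depressing
learned pixels and ends with a 7% pattern-pixel error despite ~8× more
device programming operations.

Other examples, one per capability:

| script | shows |
| --- | --- |
| `examples/stdp_curves.py` | soft-bound vs classical STDP across weight states |
| `examples/waveform_overlap.py` | SET/RESET/no-op windows of the 1T1R pulse overlap |
| `examples/single_pattern.py` | greedy vs conventional single-pattern learning |
| `examples/synthetic_classification.py` | full unsupervised pipeline + accuracy |
| `examples/variation_and_failures.py` | defect probability, variation sweep, stuck-device yield |
| `examples/mnist_full.py` | full-scale MNIST run (needs locally downloaded IDX files) |

All library-level experiments run download-free on synthetic sparse
patterns (`memstdp.data_io`), which also round-trip through the real MNIST
IDX container format.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes from scratch, via the device model's Monte-Carlo sampler, the
percentage of synapses that cannot be programmed properly in at least one
direction (a sampled potentiation or depression amplitude going negative)
when both STDP amplitudes carry 50% device-to-device relative variation,
over 10⁶ devices, and writes it as JSON. The closed-form reference is
100·(1 − Φ(2)²) ≈ 4.50%.

See `docs/methods.md` for the model assumptions, parameter rationale and
known limitations.
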