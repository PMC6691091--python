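# Methods

## Model overview

`memstdp` simulates a two-layer spiking network: an input layer of Poisson
neurons (one per pixel), a fully connected crossbar of memristive
synapses, and an output layer of leaky-integrate-and-fire (LIF) neurons
with winner-take-all (WTA) inhibition and homeostatic thresholds. Synaptic
plasticity follows a soft-bound STDP rule whose parameters are those
fitted to measured 1T1R RRAM switching; all device non-idealities
(variation, disorder, stuck cells) are modeled at the parameter level, not
at the filament-physics level.

## Synapse model (`device`)

Weight = conductance in μS. Soft-bound STDP:

ΔW = A₊ (W_max − W) e^(−Δt/τ₊) for Δt > 0, and
ΔW = −A₋ (W − W_min) e^(−|Δt|/τ₋) for Δt < 0, Δt in ns.

Defaults: A₊ = 1.0, A₋ = 0.6, τ₊ = τ₋ = 150 ns, W_min = 10 μS,
W_max = 50 μS. Numerical choices:

- **Δt = 0** (pre and post in the same 50 ns step) is treated as
  potentiation with e⁰ = 1: a same-step pre spike contributed to the
  firing. The rule itself only defines Δt ≠ 0.
- **Variation draws are untruncated.** D2D: each varied parameter is drawn
  once per device from N(μ, (σ/μ·μ)²) before a run; C2C: redrawn around
  the device's D2D reference at *every* update event. A negative sampled
  amplitude is applied as a wrong-direction update — that is the modeled
  programming disorder, so clipping the draws would erase the effect under
  study. Only weights are clipped, to the device's own [min, max] bounds.
- A device whose sampled W_max ≤ W_min is **stuck** at its initial weight
  (as is an explicitly failed fraction of the array); stuck devices ignore
  updates and decay but still conduct.
- Update order within a timestep is fixed (oldest pairing, then ascending
  input index, then output index) so clipping and C2C draws are
  bit-reproducible.
- Randomness: one master seed, with named independent substreams (via
  `SeedSequence` spawn keys) for D2D sampling, C2C sampling, failure
  selection, weight initialization, encoding and inference, so changing
  one consumer cannot shift another's stream.

## Pulse-overlap analysis (`waveform`)

The published pulse *levels* and widths are known (V_BL⁺ = 0.6 V,
V_BL⁻ = −1.0 V, V_SL⁺ = 1.3 V, V_SL⁻ = −1.0 V; 500/50 ns widths, 20 ns
transitions) but the exact section ordering inside each pulse is not. The
default layout anchors each spike time at its pulse's negative→positive
transition (BL: negative then positive; SL: negative/gate-SET then
positive/gate-RESET). This is the unique ordering of this family for which
a post spike slightly *after* the pre gives a SET (peak
V_BL⁺ + |V_SL⁻| = 1.6 V) and slightly *before* gives a RESET (peak
V_SL⁺ + |V_BL⁻| = 2.3 V) — i.e. classification is antisymmetric in the
lag, consistent with biological STDP. An alternative onset-aligned layout
remains available (`PulseSpec(align="onset")`) for exploring other
orderings. Default switching thresholds (SET 1.5 V, RESET 2.0 V) sit
strictly between the isolated-pulse peaks (1.0/1.3 V) and the full-overlap
peaks, so a lone spike never programs a device. Peaks are measured only on
gate plateau samples; ramps are excluded. The overlap voltage is *not*
translated into a quantitative ΔW — the network applies the STDP rule
directly; the waveform module documents the circuit-level feasibility.

## Encoding (`encoding`)

Images are normalized by total intensity *before* phase scaling; per-step
firing probability of pixel i is f_phase · Ĩᵢ, clipped to 1 (clipping is
only reachable for near-blank images). With f_pattern = 1 on a uniform
784-pixel image the per-neuron rate is 1/(50 ns · 784) ≈ 25.5 kHz. With
f_background = 7 the analogous background rate is 178.6 kHz; a published
figure of ~128 kHz would correspond to a factor ≈5 and is not used — the
stated factor 7 is. All-zero images (or all-255 images in the background
phase) raise an error rather than silently emitting a uniform stimulus.

## Output layer (`network`)

V_j ← V_j·e^(−Δt/τ_mem) + gain·Σᵢ W_ij·sᵢ with τ_mem = 10 μs, rest 0 V,
initial threshold 0.4 V, refractory disabled. The current-to-voltage
conversion is not specified by the device measurements, so the **gain** is
a model choice: 1/300 V/μS makes one spike through a mid-range (30 μS)
synapse worth 0.1 V, i.e. ≈4 coincident mid-strength spikes reach
threshold within the decay time. WTA: among neurons above threshold the
largest margin V − θ fires ("exceeds its threshold the most"); exact ties
go to the lowest index; every firing resets *all* potentials.

Homeostasis: θ_j += 0.1·(A_j − T) at each image boundary, A_j = neuron j's
spikes per timestep over the last 1000 images (all images so far during
warm-up). A is **per neuron**, since the threshold is per neuron. The
target T is not published; the default T = 10⁻⁴ spikes/step/neuron is ≈one
spike per image shared across 50 neurons at ~200 steps/image. Thresholds
are floored at rest + 0.01 V to prevent runaway decreases of silent
neurons.

## Training (`training`)

Greedy mode per image: pattern phase runs to the first post spike (cap 200
steps = 10 μs); on a spike at t_post every pattern pre spike with
t_post − t_pre ∈ {0, …, 3} (window 4 steps) contributes one potentiation
update to the winner's column only; the stimulus switches immediately to
the complement for 10 steps with output firing disabled and potentials
frozen, and background pre spikes with t − t_post ∈ {1, …, 4} contribute
depression updates. No post spike ⇒ no updates and no background phase.
All-to-all pairing within the window, applied sequentially with soft-bound
clipping between updates. The published text also contains a wider
"|Δt| ≤ 2τ" (6-step) window; 4 steps is adopted and the window is a
config knob. Note an update-count estimate of 6×3×1 per image appearing in
the endurance accounting implies the 6-step window; `update_ops_ratio`
reproduces the published reduction factor 500 by rounding the greedy
estimate to the nearest ten (6·3·1 = 18 ≈ 20).

Conventional baseline: fixed 210-step stimulation of the original image
only, multiple post spikes allowed (WTA still per step), same pair window
in both directions (post-then-pre pairs depress), plus multiplicative
self-decay of every working synapse toward its floor by 10⁻⁴ per step — a
simplified, clearly-labeled stand-in for published self-decay schemes, not
a faithful reproduction of any specific one.

## Inference (`inference`)

Weights and thresholds frozen; WTA and greedy stopping active; no
background phase; step cap = the training pattern cap (200). Replaying the
training set, the first-firing neuron earns 1/(firing step, 1-based) for
the image's true label; each neuron takes its argmax label (ties → lowest
label), never-firing neurons are unassigned and their predictions count as
errors. Firing time is measured in 1-based step indices (no published
unit; 1-based avoids division by zero). Inference uses the same stochastic
Poisson encoder as training. Pixel-error metrics binarize at the weight
midpoint (W_min + W_max)/2 and call a target pixel "pattern" iff its
intensity is > 0; neither threshold is published, both are recorded here.

## Synthetic data (`data_io`)

The generator emulates what the encoder assumes about handwritten-digit
data: a sparse bright pattern (default 15% of pixels at 255) on a dominant
dark background (default intensity 10), one fixed random template per
class, truncated Gaussian pixel noise (σ = 8), 28×28 by default. It does
**not** reproduce MNIST's stroke geometry, class overlap or intensity
histogram — random templates are nearly orthogonal, so classification
accuracies on synthetic data are far higher than on MNIST and are never
compared against published accuracy tables; green tests on synthetic data
establish the *mechanics* (single-spike guarantee, polarization of
weights, counts, robustness orderings), not MNIST-scale performance.
Full-scale claims (75–79% test accuracy, ~160-step mean pattern phase,
<200 max update count) are reachable only via `examples/mnist_full.py`
with locally provided IDX files. Synthetic datasets write and read the
real IDX container so the whole pipeline exercises the production format.

## Experiments (`experiments`)

Reduced-scale defaults (hundreds–thousands of synthetic images, 4–20
output neurons, 2 replicates) keep every sweep minutes-fast on one CPU;
absolute accuracies at this scale differ from full-scale tables, so sweep
tests assert orderings/trends (accuracy non-increasing in variation,
combined ≤ single scope, failure tolerance) rather than absolute values.
Every sweep cell derives its own seed from (master seed, cell name), so
any cell is independently regenerable.

## Known limitations

- No filament-level physics, no transistor I–V or IR-drop model; variation
  enters only through the four STDP parameters.
- The waveform overlap magnitude is not mapped onto the exponential
  Δt-dependence of ΔW; the two modules describe the same hardware at
  different abstraction levels.
- The conventional baseline is a simplified reference, tuned for nothing
  beyond using the same device model and window.
- Single layer only; no supervised or reward-modulated variants.
- With a fully stuck array, labeling the frozen random projection can
  still exceed chance on easy synthetic tasks; "failure destroys
  learning" statements are therefore tested as orderings, not as
  chance-level equalities.
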