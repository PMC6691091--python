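"""Leaky-integrate-and-fire output layer with WTA inhibition and homeostasis.

Membrane potentials integrate synaptic current and decay exponentially with
τ_mem; a neuron whose potential exceeds its (adaptive) threshold fires.
Lateral inhibition is winner-take-all: at most one neuron fires per
timestep — the one exceeding its threshold by the largest margin — and a
firing event resets *every* potential to rest.  Homeostasis slowly adapts
each neuron's threshold toward a common target firing rate, measured over a
sliding window of recent images, so output neurons share the stimuli
instead of a few winners dominating.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = ["LifConfig", "LifLayerState", "lif_step", "homeostasis_update"]


@dataclass(frozen=True)
class LifConfig:
    tau_mem: float = 10_000.0  # ns (10 us)
    v_rest: float = 0.0  # V
    v_th_init: float = 0.4  # V
    #: membrane increment per spike per μS of synaptic conductance; 1/300
    #: V/μS puts one spike through a mid-range 30 μS synapse at 0.1 V, so a
    #: handful of coincident pattern spikes reach threshold within the decay
    #: time (the underlying current-to-voltage conversion is not modelled).
    gain: float = 1.0 / 300.0
    homeo_rate: float = 0.1
    homeo_window: int = 1000  # images
    #: target spikes per timestep per neuron; ≈ one spike per image shared
    #: across 50 neurons at ~200 steps per image.
    homeo_target: float = 1e-4
    refractory_steps: int = 0  # disabled for simplicity
    #: thresholds never adapt below v_rest + this floor
    threshold_floor: float = 0.01

    def __post_init__(self) -> None:
        if self.tau_mem <= 0:
            raise ValueError("tau_mem must be positive")
        if self.v_th_init <= self.v_rest:
            raise ValueError("v_th_init must exceed v_rest")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.homeo_window < 1:
            raise ValueError("homeo_window must be >= 1")


@dataclass
class LifLayerState:
    """Mutable state of one LIF output layer."""

    potentials: np.ndarray
    thresholds: np.ndarray
    #: per-image (spike counts per neuron, steps) pairs, bounded by homeo_window
    spike_history: deque = field(default_factory=deque)
    last_post_step: np.ndarray | None = None
    #: spikes of each neuron accumulated within the current image
    current_spikes: np.ndarray | None = None
    refractory_left: np.ndarray | None = None

    @classmethod
    def create(cls, n_neurons: int, config: LifConfig) -> "LifLayerState":
        return cls(
            potentials=np.full(n_neurons, config.v_rest, dtype=float),
            thresholds=np.full(n_neurons, config.v_th_init, dtype=float),
            spike_history=deque(maxlen=None),
            last_post_step=np.full(n_neurons, -1, dtype=np.int64),
            current_spikes=np.zeros(n_neurons, dtype=np.int64),
            refractory_left=np.zeros(n_neurons, dtype=np.int64),
        )

    @property
    def n_neurons(self) -> int:
        return self.potentials.shape[0]


def lif_step(
    state: LifLayerState,
    input_spikes: np.ndarray,
    weights: np.ndarray,
    config: LifConfig,
    timestep: float = 50.0,
    step_index: int = 0,
) -> int | None:
    """Advance the layer one timestep; returns the fired neuron index or None.

    V_j ← V_j·exp(−Δt/τ_mem) + gain·Σ_i W_ij·s_i.  Candidates are neurons
    with V_j > θ_j; the one maximizing V_j − θ_j fires (ties → lowest
    index), all potentials reset to rest, and the spike is recorded.
    """
    s = np.asarray(input_spikes)
    if s.shape[0] != weights.shape[0] or weights.shape[1] != state.n_neurons:
        raise ValueError(
            f"dimension mismatch: inputs {s.shape[0]}, weights {weights.shape}, "
            f"neurons {state.n_neurons}"
        )
    decay = np.exp(-timestep / config.tau_mem)
    state.potentials *= decay
    if s.any():
        state.potentials += config.gain * (s.astype(float) @ weights)
    if config.refractory_steps > 0:
        held = state.refractory_left > 0
        state.potentials[held] = config.v_rest
        state.refractory_left[held] -= 1

    margins = state.potentials - state.thresholds
    candidates = np.flatnonzero(margins > 0)
    if candidates.size == 0:
        return None
    winner = int(candidates[np.argmax(margins[candidates])])
    state.potentials[:] = config.v_rest
    state.current_spikes[winner] += 1
    state.last_post_step[winner] = step_index
    if config.refractory_steps > 0:
        state.refractory_left[winner] = config.refractory_steps
    return winner


def end_image(state: LifLayerState, steps_used: int, config: LifConfig) -> None:
    """Close out one image: push its spike counts into the sliding history."""
    state.spike_history.append((state.current_spikes.copy(), int(steps_used)))
    while len(state.spike_history) > config.homeo_window:
        state.spike_history.popleft()
    state.current_spikes[:] = 0


def homeostasis_update(state: LifLayerState, config: LifConfig) -> LifLayerState:
    """Adapt thresholds at an image boundary: θ_j += rate·(A_j − T).

    A_j is neuron j's spikes per timestep averaged over the last
    ``homeo_window`` images (all images seen so far during warm-up).
    Thresholds are floored at v_rest + threshold_floor so silent neurons
    cannot drive their threshold arbitrarily negative.
    """
    if not state.spike_history:
        return state
    spikes = np.sum([h[0] for h in state.spike_history], axis=0)
    steps = sum(h[1] for h in state.spike_history)
    if steps <= 0:
        return state
    a = spikes / steps
    state.thresholds += config.homeo_rate * (a - config.homeo_target)
    np.maximum(state.thresholds, config.v_rest + config.threshold_floor,
               out=state.thresholds)
    return state
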