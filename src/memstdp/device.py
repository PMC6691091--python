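"""Soft-bound STDP synapse model for memristive (RRAM) crossbar arrays.

The synapse is a 1T1R memristor whose conductance ``W`` (μS) plays the role
of the weight.  A pre/post spike pair separated by Δt = t_post − t_pre (ns)
changes the conductance with a *soft bound*: the update magnitude shrinks as
the weight approaches its ceiling ``W_max`` (potentiation) or floor ``W_min``
(depression),

    ΔW =  A+ · (W_max − W) · exp(−Δt/τ+)      for Δt > 0,
    ΔW = −A− · (W − W_min) · exp(−|Δt|/τ−)    for Δt < 0,

which matches the measured behaviour of HfOx/TaOy 1T1R cells: devices in a
high-resistance state show larger relative SET changes than devices already
near the conductance ceiling, and symmetrically for RESET.

Device non-idealities are modelled at the parameter level:

* **D2D (device-to-device)** — each synapse gets its own reference copy of
  the parameters, drawn once per simulation from Normal(μ, (σ/μ·μ)²).
* **C2C (cycle-to-cycle)** — at every update event the effective parameters
  are re-drawn around the device's D2D reference values.
* **Failures / defects** — draws are *not* truncated: a negative sampled
  amplitude is applied as-is (a potentiation/depression "disorder"), a
  device whose sampled ``w_max`` falls below its ``w_min`` is stuck at its
  initial conductance, and an explicit ``failure_rate`` fraction of devices
  is stuck outright.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from ._rng import substream

__all__ = [
    "StdpParams",
    "VariationSpec",
    "SynapseArray",
    "stdp_delta",
    "stdp_relative",
    "classical_stdp_relative",
    "sample_d2d",
    "perturb_c2c",
    "apply_update",
]

#: parameter names that VariationSpec.varied_params may contain
_PARAM_NAMES = ("a_plus", "a_minus", "w_max", "w_min")


@dataclass(frozen=True)
class StdpParams:
    """Nominal soft-bound STDP parameters.

    Conductances in μS, time constants in ns.  Defaults are the values
    fitted to the measured 1T1R STDP characteristic.
    """

    a_plus: float = 1.0
    a_minus: float = 0.6
    tau_plus: float = 150.0
    tau_minus: float = 150.0
    w_max: float = 50.0
    w_min: float = 10.0

    def __post_init__(self) -> None:
        for name in ("a_plus", "a_minus", "tau_plus", "tau_minus", "w_max", "w_min"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("time constants must be positive")

    def validate_nominal(self) -> "StdpParams":
        """Check the stricter invariants that hold for *nominal* parameters.

        Per-device effective values sampled under variation may violate
        these (that is the modelled defect), so they are not enforced in
        ``__post_init__``.
        """
        if self.w_max <= self.w_min:
            raise ValueError("nominal w_max must exceed w_min")
        if self.a_plus <= 0 or self.a_minus <= 0:
            raise ValueError("nominal amplitudes must be positive")
        return self


@dataclass(frozen=True)
class VariationSpec:
    """Gaussian parameter-dispersion and failure model, levels are σ/μ."""

    level_c2c: float = 0.0
    level_d2d: float = 0.0
    varied_params: tuple[str, ...] = ("a_plus", "a_minus", "w_max", "w_min")
    failure_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.level_c2c < 0 or self.level_d2d < 0:
            raise ValueError("variation levels must be >= 0")
        if not 0.0 <= self.failure_rate <= 1.0:
            raise ValueError("failure_rate must lie in [0, 1]")
        bad = set(self.varied_params) - set(_PARAM_NAMES)
        if bad:
            raise ValueError(f"unknown varied_params: {sorted(bad)}")
        object.__setattr__(self, "varied_params", tuple(self.varied_params))


def _check_finite(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{name} must be finite, got {v!r}")


def stdp_delta(w, delta_t, params: StdpParams):
    """Soft-bound STDP conductance change ΔW in μS.

    Δt = 0 (pre and post in the same timestep) is treated as potentiation
    with exp(0) = 1: a same-step pre-spike contributed to the firing.
    Accepts scalars or broadcastable arrays.
    """
    w = np.asarray(w, dtype=float)
    delta_t = np.asarray(delta_t, dtype=float)
    _check_finite(w=w, delta_t=delta_t)
    pot = params.a_plus * (params.w_max - w) * np.exp(
        -np.abs(delta_t) / params.tau_plus
    )
    dep = -params.a_minus * (w - params.w_min) * np.exp(
        -np.abs(delta_t) / params.tau_minus
    )
    out = np.where(delta_t >= 0, pot, dep)
    return out.item() if out.ndim == 0 else out


def stdp_relative(w, delta_t, params: StdpParams):
    """Relative soft-bound change ΔW/W (dimensionless)."""
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("stdp_relative requires w > 0")
    out = np.asarray(stdp_delta(w, delta_t, params)) / w
    return out.item() if out.ndim == 0 else out


def classical_stdp_relative(delta_t, params: StdpParams):
    """Classical (weight-independent) STDP relative change ΔW/W.

    The classical rule expects relative changes that do not depend on the
    current weight state — a poor match for memristors, kept as reference.
    """
    delta_t = np.asarray(delta_t, dtype=float)
    _check_finite(delta_t=delta_t)
    pot = params.a_plus * np.exp(-np.abs(delta_t) / params.tau_plus)
    dep = -params.a_minus * np.exp(-np.abs(delta_t) / params.tau_minus)
    out = np.where(delta_t >= 0, pot, dep)
    return out.item() if out.ndim == 0 else out


@dataclass
class SynapseArray:
    """A crossbar of memristive synapses with per-device effective parameters.

    ``weights`` has shape (n_inputs, n_outputs) in μS.  ``device_params``
    maps each parameter name to an array of the same shape holding the
    D2D-sampled reference values (equal to the nominal values when the
    parameter is not varied).  ``stuck_mask`` marks failed devices that hold
    their initial conductance forever; ``update_counts`` counts update
    *attempts* on working devices (endurance accounting).
    """

    weights: np.ndarray
    device_params: dict[str, np.ndarray]
    stuck_mask: np.ndarray
    update_counts: np.ndarray
    nominal: StdpParams
    variation: VariationSpec
    rng: np.random.Generator = field(repr=False)

    @property
    def n_inputs(self) -> int:
        return self.weights.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.weights.shape[1]

    def effective_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Elementwise (lower, upper) clipping bounds per device."""
        lo = np.minimum(self.device_params["w_min"], self.device_params["w_max"])
        hi = np.maximum(self.device_params["w_min"], self.device_params["w_max"])
        return lo, hi

    def copy(self) -> "SynapseArray":
        import copy as _copy

        return SynapseArray(
            weights=self.weights.copy(),
            device_params={k: v.copy() for k, v in self.device_params.items()},
            stuck_mask=self.stuck_mask.copy(),
            update_counts=self.update_counts.copy(),
            nominal=self.nominal,
            variation=self.variation,
            rng=_copy.deepcopy(self.rng),
        )

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Snapshot to a self-describing .npz (shape, units and seed state)."""
        import json

        state = json.dumps(self.rng.bit_generator.state)
        np.savez(
            path,
            weights=self.weights,
            stuck_mask=self.stuck_mask,
            update_counts=self.update_counts,
            rng_state=np.frombuffer(state.encode(), dtype=np.uint8),
            units=np.array(["weights:uS", "time:ns"]),
            **{f"param_{k}": v for k, v in self.device_params.items()},
        )


def sample_d2d(
    nominal: StdpParams,
    spec: VariationSpec,
    n_in: int,
    n_out: int,
    seed: int,
    *,
    init_weights: np.ndarray | None = None,
) -> SynapseArray:
    """Build a SynapseArray with D2D-sampled parameters and failure mask.

    Each varied parameter is drawn once per synapse from
    Normal(μ, (level_d2d·μ)²), *untruncated* — negative amplitudes model
    devices that cannot be programmed properly in one direction.  Devices
    with sampled ``w_max`` ≤ ``w_min`` are stuck at their initial value, and
    a uniformly chosen ``failure_rate`` fraction of devices is stuck too.

    Initial weights are uniform in [w_min, w_max] (nominal bounds) unless
    ``init_weights`` is given.  The returned array carries an independent
    "c2c" substream for per-update parameter draws.
    """
    nominal.validate_nominal()
    shape = (int(n_in), int(n_out))
    rng_d2d = substream(seed, "d2d")
    rng_init = substream(seed, "init")

    params: dict[str, np.ndarray] = {}
    for name in _PARAM_NAMES:
        mu = getattr(nominal, name)
        if spec.level_d2d > 0 and name in spec.varied_params:
            params[name] = rng_d2d.normal(mu, spec.level_d2d * abs(mu), size=shape)
        else:
            params[name] = np.full(shape, mu, dtype=float)

    stuck = params["w_max"] <= params["w_min"]
    if spec.failure_rate > 0:
        n = shape[0] * shape[1]
        n_fail = int(round(spec.failure_rate * n))
        idx = substream(seed, "failures").choice(n, size=n_fail, replace=False)
        stuck.flat[idx] = True

    if init_weights is None:
        weights = rng_init.uniform(nominal.w_min, nominal.w_max, size=shape)
    else:
        weights = np.array(init_weights, dtype=float)
        if weights.shape != shape:
            raise ValueError("init_weights shape mismatch")

    return SynapseArray(
        weights=weights,
        device_params=params,
        stuck_mask=stuck,
        update_counts=np.zeros(shape, dtype=np.int64),
        nominal=nominal,
        variation=spec,
        rng=substream(seed, "c2c"),
    )


def perturb_c2c(
    device: StdpParams,
    spec: VariationSpec,
    rng: np.random.Generator,
) -> StdpParams:
    """Per-update-event parameter draw around the D2D reference values.

    Draws Normal(ref, (level_c2c·ref)²) for each varied parameter,
    untruncated: a negative sampled amplitude IS applied, realizing a
    wrong-direction (disorder) update for that event.
    """
    if spec.level_c2c == 0:
        return device
    kw = {}
    for name in spec.varied_params:
        ref = getattr(device, name)
        kw[name] = float(rng.normal(ref, spec.level_c2c * abs(ref)))
    return replace(device, **kw)


def _device_params_at(array: SynapseArray, i: int, j: int) -> StdpParams:
    return StdpParams(
        a_plus=float(array.device_params["a_plus"][i, j]),
        a_minus=float(array.device_params["a_minus"][i, j]),
        tau_plus=array.nominal.tau_plus,
        tau_minus=array.nominal.tau_minus,
        w_max=float(array.device_params["w_max"][i, j]),
        w_min=float(array.device_params["w_min"][i, j]),
    )


def apply_update(
    array: SynapseArray,
    input_index: int,
    output_index: int,
    delta_t: float,
    spec: VariationSpec | None = None,
) -> SynapseArray:
    """Apply one STDP update event to synapse (input_index, output_index).

    Mutates ``array`` in place and returns it.  Stuck devices are a no-op
    (they "do not respond to any input"); otherwise the weight moves by the
    soft-bound ΔW under C2C-perturbed effective parameters and is clipped to
    the device's own bounds.  The update counter increments for every
    non-stuck invocation.
    """
    i, j = int(input_index), int(output_index)
    if not (0 <= i < array.n_inputs and 0 <= j < array.n_outputs):
        raise IndexError(f"synapse index ({i}, {j}) out of range")
    if array.stuck_mask[i, j]:
        return array
    if spec is None:
        spec = array.variation

    dev = _device_params_at(array, i, j)
    eff = perturb_c2c(dev, spec, array.rng)
    dw = stdp_delta(array.weights[i, j], delta_t, eff)
    lo = min(eff.w_min, eff.w_max)
    hi = max(eff.w_min, eff.w_max)
    array.weights[i, j] = float(np.clip(array.weights[i, j] + dw, lo, hi))
    array.update_counts[i, j] += 1
    return array


def apply_update_events(
    array: SynapseArray,
    events: Iterable[tuple[int, int, float]],
) -> SynapseArray:
    """Apply a sequence of (input, output, Δt ns) events in the given order.

    The caller fixes the order (the trainer uses oldest pairing first, then
    ascending input index, then ascending output index) so that clipping and
    C2C draws are reproducible.
    """
    for i, j, dt in events:
        apply_update(array, i, j, dt)
    return array
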