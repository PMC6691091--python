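"""1T1R pulse-overlap analysis: V_CELL traces and SET/RESET classification.

A pre-spike drives the bit line (BL) and a post-spike drives the source
line (SL) together with a synchronized gate pulse.  The voltage across the
memristor is V_CELL(t) = V_BL(t) − V_SL(t); whether an overlap programs the
device depends on the peak V_CELL reached *while the gate sits at the
matching level* (a low V_G enables SET, a high V_G enables RESET).

Pulse layout (default, ``align="transition"``): each spike's nominal time
sits at the negative→positive section boundary of its pulse,

* BL pre-spike — negative section for width_bl/2 before the spike time,
  positive section for width_bl/2 after it;
* SL post-spike — negative section (gate at v_g_set) for width_sl/2 before
  the spike time, positive section (gate at v_g_reset) after it.

A post-spike slightly *after* the pre-spike then puts its SL-negative
section over the BL-positive section (V_CELL up to V_BL+ + |V_SL−|, a SET,
i.e. potentiation for Δt > 0), while a post-spike slightly *before* puts
its SL-positive section over the BL-negative section (V_CELL down to
−(V_SL+ + |V_BL−|), a RESET — depression for Δt < 0).  ``align="onset"``
instead starts each pulse at the spike time with the positive BL section
first, for exploring alternative orderings.

All sections are joined by linear ramps of duration ``transition``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PulseSpec", "OverlapResult", "v_cell_trace", "classify_operation"]


@dataclass(frozen=True)
class PulseSpec:
    """Pulse-shaping voltages (V) and timings (ns) for BL, SL and gate.

    Defaults are the measured-device waveform: V_BL+ = 0.6 V,
    V_BL− = −1.0 V, V_SL+ = 1.3 V, V_SL− = −1.0 V, widths 500 ns (BL) and
    50 ns (SL/gate, synchronized), 20 ns transitions.
    """

    v_bl_pos: float = 0.6
    v_bl_neg: float = -1.0
    v_sl_pos: float = 1.3
    v_sl_neg: float = -1.0
    v_g_set: float = 1.0
    v_g_reset: float = 4.0
    width_bl: float = 500.0
    width_sl: float = 50.0
    transition: float = 20.0
    align: str = "transition"  # or "onset"

    def __post_init__(self) -> None:
        if self.width_bl <= 0 or self.width_sl <= 0:
            raise ValueError("pulse widths must be positive")
        if self.transition < 0:
            raise ValueError("transition must be >= 0")
        if not (self.v_bl_neg <= 0 <= self.v_bl_pos):
            raise ValueError("BL levels must satisfy v_bl_neg <= 0 <= v_bl_pos")
        if not (self.v_sl_neg <= 0 <= self.v_sl_pos):
            raise ValueError("SL levels must satisfy v_sl_neg <= 0 <= v_sl_pos")
        if self.align not in ("transition", "onset"):
            raise ValueError("align must be 'transition' or 'onset'")


@dataclass(frozen=True)
class OverlapResult:
    """Peak programming voltages seen in each gate window and the verdict."""

    peak_set_voltage: float
    peak_reset_magnitude: float
    operation: str  # "SET" | "RESET" | "NONE"
    ambiguous: bool = False  # both thresholds exceeded; classified by margin


def _piecewise(t: np.ndarray, sections: list[tuple[float, float, float]],
               transition: float) -> np.ndarray:
    """Sample a pulse defined by (start, end, level) sections, baseline 0.

    Level changes are linear ramps of duration ``transition`` centred on
    each section boundary (including the leading and trailing edges).
    """
    # breakpoints: (time, level-after)
    edges: list[tuple[float, float]] = []
    prev_level = 0.0
    for start, end, level in sections:
        edges.append((start, level))
        prev_level = level
        last_end = end
    edges.append((last_end, 0.0))

    xs: list[float] = []
    ys: list[float] = []
    level = 0.0
    h = transition / 2.0
    for when, new_level in edges:
        if transition == 0:
            xs.extend([when, when])
            ys.extend([level, new_level])
        else:
            xs.extend([when - h, when + h])
            ys.extend([level, new_level])
        level = new_level
    return np.interp(t, xs, ys, left=0.0, right=0.0)


def _sections(spec: PulseSpec, t_spike: float, which: str):
    """Section layouts for one pulse, anchored at the spike time."""
    if which == "bl":
        w, neg, pos = spec.width_bl, spec.v_bl_neg, spec.v_bl_pos
    else:
        w, neg, pos = spec.width_sl, spec.v_sl_neg, spec.v_sl_pos
    if spec.align == "transition":
        first = (t_spike - w / 2, t_spike, neg)
        second = (t_spike, t_spike + w / 2, pos)
    else:  # onset: pulse starts at the spike time, positive BL section first
        if which == "bl":
            first = (t_spike, t_spike + w / 2, pos)
            second = (t_spike + w / 2, t_spike + w, neg)
        else:
            first = (t_spike, t_spike + w / 2, neg)
            second = (t_spike + w / 2, t_spike + w, pos)
    return [first, second]


def _gate_sections(spec: PulseSpec, t_post: float):
    """Gate level tracks the SL sections: v_g_set with SL−, v_g_reset with SL+."""
    sl = _sections(spec, t_post, "sl")
    (s0, e0, lvl0), (s1, e1, lvl1) = sl
    g0 = spec.v_g_set if lvl0 == spec.v_sl_neg else spec.v_g_reset
    g1 = spec.v_g_set if lvl1 == spec.v_sl_neg else spec.v_g_reset
    return [(s0, e0, g0), (s1, e1, g1)]


def v_cell_trace(
    pulses: PulseSpec,
    delta_t: float,
    resolution: float = 1.0,
):
    """Sample V_CELL(t) = V_BL(t) − V_SL(t) and the gate level over time.

    The pre-spike is at t = 0 and the post-spike at t = Δt (ns).  Returns
    ``(t, v_cell, gate)`` arrays covering both pulses plus their ramps.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    bl = _sections(pulses, 0.0, "bl")
    sl = _sections(pulses, float(delta_t), "sl")
    pad = pulses.transition + resolution
    t0 = min(s[0] for s in bl + sl) - pad
    t1 = max(s[1] for s in bl + sl) + pad
    t = np.arange(t0, t1 + resolution, resolution)
    v_bl = _piecewise(t, bl, pulses.transition)
    v_sl = _piecewise(t, sl, pulses.transition)
    gate = _piecewise(t, _gate_sections(pulses, float(delta_t)), pulses.transition)
    return t, v_bl - v_sl, gate


def trace_to_csv(path, t: np.ndarray, v_cell: np.ndarray) -> None:
    """Export a (time ns, volts) two-column CSV."""
    np.savetxt(path, np.column_stack([t, v_cell]), delimiter=",",
               header="time_ns,v_cell_V", comments="")


def classify_operation(
    pulses: PulseSpec,
    delta_t: float,
    set_threshold: float = 1.5,
    reset_threshold: float = 2.0,
    resolution: float = 1.0,
) -> OverlapResult:
    """Classify a pre/post overlap at Δt as SET, RESET or NONE.

    ``peak_set_voltage`` is the maximum positive V_CELL sampled while the
    gate sits at its SET plateau; ``peak_reset_magnitude`` the maximum
    |negative V_CELL| while the gate sits at its RESET plateau (ramp samples
    are excluded).  Default thresholds (1.5 V SET / 2.0 V RESET) lie strictly
    between the isolated-pulse and full-overlap analytic magnitudes, so a
    lone pulse never switches the device.  If both thresholds are exceeded
    the larger threshold margin wins and the result is flagged ambiguous.
    """
    if set_threshold <= 0 or reset_threshold <= 0:
        raise ValueError("thresholds must be positive")
    t, v, gate = v_cell_trace(pulses, delta_t, resolution)
    tol = 1e-9
    in_set = np.abs(gate - pulses.v_g_set) < tol
    in_reset = np.abs(gate - pulses.v_g_reset) < tol
    peak_set = float(np.max(v[in_set], initial=0.0))
    peak_set = max(peak_set, 0.0)
    peak_reset = float(np.max(-v[in_reset], initial=0.0))
    peak_reset = max(peak_reset, 0.0)

    set_hit = peak_set >= set_threshold
    reset_hit = peak_reset >= reset_threshold
    if set_hit and reset_hit:
        op = "SET" if (peak_set - set_threshold) >= (peak_reset - reset_threshold) \
            else "RESET"
        return OverlapResult(peak_set, peak_reset, op, ambiguous=True)
    if set_hit:
        return OverlapResult(peak_set, peak_reset, "SET")
    if reset_hit:
        return OverlapResult(peak_set, peak_reset, "RESET")
    return OverlapResult(peak_set, peak_reset, "NONE")
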