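"""Poisson rate coding of images with pattern/background two-phase scheme.

Each pixel maps to one input (Poisson) neuron.  The image is normalized by
its *total* intensity, so per-step firing probabilities sum to a phase
activity factor: f_pattern (default 1 expected input-layer spike per step)
while the original image is shown, f_background (default 7) while its
complement (255 − I) is shown.  Spikes are independent Bernoulli trials per
neuron per 50 ns timestep — a discrete-time Poisson approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EncoderConfig",
    "Stimulus",
    "normalize",
    "complement",
    "make_stimulus",
    "sample_spikes",
]


@dataclass(frozen=True)
class EncoderConfig:
    timestep: float = 50.0  # ns
    f_pattern: float = 1.0  # expected input-layer spikes per step, pattern phase
    f_background: float = 7.0  # same, background phase
    pattern_max_steps: int = 200  # 10 us cap on the pattern phase
    background_steps: int = 10  # fixed 500 ns background phase

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.f_pattern < 0 or self.f_background < 0:
            raise ValueError("phase factors must be >= 0")
        if self.pattern_max_steps < 1 or self.background_steps < 1:
            raise ValueError("phase durations must be >= 1 step")


@dataclass(frozen=True)
class Stimulus:
    """Per-step, per-neuron firing probabilities for one phase of one image."""

    probabilities: np.ndarray
    phase: str  # "pattern" | "background"

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "probabilities", p)
        if self.phase not in ("pattern", "background"):
            raise ValueError("phase must be 'pattern' or 'background'")


def _flat(image) -> np.ndarray:
    """Row-major flattening, top-left origin; accepts vectors or H×W arrays."""
    arr = np.asarray(image, dtype=float)
    return arr.reshape(-1)


def normalize(image) -> np.ndarray:
    """Normalize pixel intensities to unit total.

    Raises on an all-zero image: a blank stimulus has no defined rate code
    (and silently emitting a uniform one would hide upstream data bugs).
    """
    v = _flat(image)
    if np.any(v < 0):
        raise ValueError("pixel intensities must be nonnegative")
    total = v.sum()
    if total <= 0:
        raise ValueError(
            "cannot normalize an all-zero image: total intensity is 0 "
            "(degenerate stimulus)"
        )
    return v / total


def complement(image, max_intensity: float = 255.0) -> np.ndarray:
    """Elementwise complement max_intensity − pixel (an involution)."""
    v = np.asarray(image, dtype=float)
    if np.any(v < 0) or np.any(v > max_intensity):
        raise ValueError(f"pixels must lie in [0, {max_intensity}]")
    return max_intensity - v


def make_stimulus(image, phase: str, config: EncoderConfig = EncoderConfig()) -> Stimulus:
    """Build the per-step firing probabilities for one phase of an image.

    pattern phase: p_i = f_pattern · Ĩ_i of the original image;
    background phase: p_i = f_background · Ĩ_i of the complement.
    Probabilities are clipped to 1 after scaling (rare, near-blank images).
    """
    if phase == "pattern":
        p = config.f_pattern * normalize(image)
    elif phase == "background":
        p = config.f_background * normalize(complement(image))
    else:
        raise ValueError("phase must be 'pattern' or 'background'")
    return Stimulus(np.clip(p, 0.0, 1.0), phase)


def expected_neuron_rate_hz(config: EncoderConfig, n_pixels: int,
                            phase: str = "pattern") -> float:
    """Mean per-neuron firing rate (Hz) for a uniform image in one phase."""
    f = config.f_pattern if phase == "pattern" else config.f_background
    return f / (n_pixels * config.timestep * 1e-9)


def sample_spikes(stimulus: Stimulus, rng: np.random.Generator) -> np.ndarray:
    """One timestep of independent Bernoulli spike draws (boolean vector)."""
    p = stimulus.probabilities
    return rng.random(p.shape) < p
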