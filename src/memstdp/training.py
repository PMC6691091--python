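"""Greedy two-phase STDP training, plus a conventional fixed-duration baseline.

Greedy training learns one image as follows: the normalized image drives
the input layer (pattern phase) until the *first* output spike, at which
point every pattern pre-spike inside the STDP window pairs with that post
spike as a potentiation event; the stimulus then switches immediately to
the complementary image (background phase) for a short fixed period with
output firing disabled, and early background pre-spikes pair with the same
post spike as depression events.  Each image therefore produces at most one
post spike, so learning stays gradual across stimuli even when a single
device update is a large fraction of the conductance range — the property
that lets coarse (≈20-level) memristors train the network.

The conventional baseline stimulates with the original image for a fixed
duration, permits multiple post spikes, uses the same pair-based STDP
window in both directions, and adds multiplicative self-decay of every
weight toward its floor to forget irrelevant inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .device import SynapseArray, apply_update
from .encoding import EncoderConfig, make_stimulus, sample_spikes
from .network import LifConfig, LifLayerState, end_image, homeostasis_update, lif_step

__all__ = [
    "TrainConfig",
    "TrainRecord",
    "greedy_train_image",
    "greedy_train_epoch",
    "conventional_train_image",
    "conventional_train_epoch",
]


@dataclass(frozen=True)
class TrainConfig:
    #: STDP pairing window in timesteps.  Potentiation pairs satisfy
    #: t_post − t_pre ∈ {0, …, window−1}; depression pairs t − t_post ∈
    #: {1, …, window}.  Narrow windows keep per-synapse update counts low.
    stdp_window_steps: int = 4
    mode: str = "greedy"  # or "conventional"
    conventional_duration_steps: int = 210
    decay_per_step: float = 1e-4  # conventional self-decay, per timestep

    def __post_init__(self) -> None:
        if self.stdp_window_steps < 1:
            raise ValueError("stdp_window_steps must be >= 1")
        if self.conventional_duration_steps < 1:
            raise ValueError("conventional_duration_steps must be >= 1")
        if self.mode not in ("greedy", "conventional"):
            raise ValueError("mode must be 'greedy' or 'conventional'")
        if not 0 <= self.decay_per_step < 1:
            raise ValueError("decay_per_step must lie in [0, 1)")


@dataclass
class ImageRecord:
    steps_used: int  # pattern-phase steps consumed
    fired: int | None  # winning neuron, or None
    n_updates: int  # STDP update operations applied (non-stuck devices)
    post_spikes: int  # post-spike count for the image


@dataclass
class TrainRecord:
    """Per-image accounting for one training run."""

    images: list[ImageRecord] = field(default_factory=list)
    total_steps: int = 0

    def append(self, rec: ImageRecord, total_steps_this_image: int) -> None:
        self.images.append(rec)
        self.total_steps += total_steps_this_image

    @property
    def n_images(self) -> int:
        return len(self.images)

    @property
    def mean_pattern_steps(self) -> float:
        return float(np.mean([r.steps_used for r in self.images]))

    @property
    def mean_updates_per_image(self) -> float:
        return float(np.mean([r.n_updates for r in self.images]))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "steps_used": [r.steps_used for r in self.images],
                "fired": [r.fired for r in self.images],
                "n_updates": [r.n_updates for r in self.images],
                "post_spikes": [r.post_spikes for r in self.images],
            }
        )

    def summary(self) -> dict:
        return {
            "n_images": self.n_images,
            "total_steps": self.total_steps,
            "mean_pattern_steps": self.mean_pattern_steps,
            "mean_updates_per_image": self.mean_updates_per_image,
        }


def stdp_pairings(
    pre_spike_steps: list[tuple[int, np.ndarray]],
    t_post: int,
    window: int,
    timestep: float,
) -> list[tuple[int, float]]:
    """Potentiation pairings for a post spike at step ``t_post``.

    ``pre_spike_steps`` holds (step, spiking input indices) entries.  Every
    pre spike with 0 ≤ t_post − t_pre < window contributes one pairing with
    Δt = (t_post − t_pre)·timestep, ordered oldest pairing first and by
    ascending input index within a step.
    """
    events: list[tuple[int, float]] = []
    for t_pre, idxs in pre_spike_steps:
        lag = t_post - t_pre
        if 0 <= lag < window:
            dt = lag * timestep
            for i in np.sort(idxs):
                events.append((int(i), dt))
    return events


def _count_applied(synapses: SynapseArray, before: int) -> int:
    return int(synapses.update_counts.sum()) - before


def greedy_train_image(
    image,
    synapses: SynapseArray,
    lif_state: LifLayerState,
    encoder: EncoderConfig,
    lif: LifConfig,
    train: TrainConfig,
    rng: np.random.Generator,
) -> ImageRecord:
    """Learn one image with the greedy pattern/background routine.

    Mutates ``synapses`` and ``lif_state`` in place; applies the
    homeostatic threshold update at the image boundary.  If no output
    neuron fires within ``pattern_max_steps`` the background phase is
    skipped and no updates occur.
    """
    window = train.stdp_window_steps
    stim = make_stimulus(image, "pattern", encoder)
    buffer: list[tuple[int, np.ndarray]] = []  # last `window` steps of pre spikes
    ops_before = int(synapses.update_counts.sum())

    fired: int | None = None
    t_post = 0
    t = 0
    for t in range(1, encoder.pattern_max_steps + 1):
        spikes = sample_spikes(stim, rng)
        buffer.append((t, np.flatnonzero(spikes)))
        if len(buffer) > window:
            buffer.pop(0)
        fired = lif_step(lif_state, spikes, synapses.weights, lif,
                         encoder.timestep, step_index=t)
        if fired is not None:
            t_post = t
            break

    steps_total = t
    if fired is not None:
        # (a) potentiation: pattern pre spikes inside the window, oldest first
        for i, dt in stdp_pairings(buffer, t_post, window, encoder.timestep):
            apply_update(synapses, i, fired, dt)
        # (b) background phase: output disabled, potentials frozen; early
        # background pre spikes pair as depression with the post spike
        bg = make_stimulus(image, "background", encoder)
        for u in range(1, encoder.background_steps + 1):
            spikes = sample_spikes(bg, rng)
            if u <= window:
                dt = -u * encoder.timestep
                for i in np.sort(np.flatnonzero(spikes)):
                    apply_update(synapses, int(i), fired, dt)
        steps_total += encoder.background_steps

    rec = ImageRecord(
        steps_used=t,
        fired=fired,
        n_updates=_count_applied(synapses, ops_before),
        post_spikes=0 if fired is None else 1,
    )
    end_image(lif_state, steps_total, lif)
    homeostasis_update(lif_state, lif)
    return rec


def conventional_train_image(
    image,
    synapses: SynapseArray,
    lif_state: LifLayerState,
    encoder: EncoderConfig,
    lif: LifConfig,
    train: TrainConfig,
    rng: np.random.Generator,
) -> ImageRecord:
    """Fixed-duration baseline: original image only, self-decay, multi-spike.

    Pair-based STDP in both directions with the same window: each post
    spike potentiates the pre spikes that preceded it within the window,
    and pre spikes arriving within the window *after* a neuron's most
    recent post spike depress that neuron's synapses.  Every timestep all
    working synapses decay multiplicatively toward their floor.
    """
    window = train.stdp_window_steps
    stim = make_stimulus(image, "pattern", encoder)
    buffer: list[tuple[int, np.ndarray]] = []
    ops_before = int(synapses.update_counts.sum())
    last_post = np.full(lif_state.n_neurons, -(10 ** 9), dtype=np.int64)
    n_posts = 0

    lo, _hi = synapses.effective_bounds()
    active = ~synapses.stuck_mask
    for t in range(1, train.conventional_duration_steps + 1):
        spikes = sample_spikes(stim, rng)
        idxs = np.flatnonzero(spikes)
        buffer.append((t, idxs))
        if len(buffer) > window:
            buffer.pop(0)
        # depression: pre after post, ascending output index per design order
        if idxs.size:
            for j in range(lif_state.n_neurons):
                lag = t - last_post[j]
                if 1 <= lag <= window:
                    dt = -lag * encoder.timestep
                    for i in np.sort(idxs):
                        apply_update(synapses, int(i), j, dt)
        fired = lif_step(lif_state, spikes, synapses.weights, lif,
                         encoder.timestep, step_index=t)
        if fired is not None:
            n_posts += 1
            last_post[fired] = t
            for i, dt in stdp_pairings(buffer, t, window, encoder.timestep):
                apply_update(synapses, i, fired, dt)
        # self-decay toward the floor (not an STDP update operation)
        if train.decay_per_step > 0:
            w = synapses.weights
            w[active] = lo[active] + (w[active] - lo[active]) * (
                1.0 - train.decay_per_step
            )

    rec = ImageRecord(
        steps_used=train.conventional_duration_steps,
        fired=None if n_posts == 0 else int(np.argmax(last_post)),
        n_updates=_count_applied(synapses, ops_before),
        post_spikes=n_posts,
    )
    end_image(lif_state, train.conventional_duration_steps, lif)
    homeostasis_update(lif_state, lif)
    return rec


def _train_epoch(
    train_image_fn,
    images,
    synapses: SynapseArray,
    lif_state: LifLayerState,
    encoder: EncoderConfig,
    lif: LifConfig,
    train: TrainConfig,
    seed: int,
    progress_every: int | None = None,
) -> TrainRecord:
    rng = substream(seed, "encode")
    record = TrainRecord()
    images = np.asarray(images)
    for k in range(images.shape[0]):
        rec = train_image_fn(images[k], synapses, lif_state, encoder, lif,
                             train, rng)
        extra = 0
        if train_image_fn is greedy_train_image and rec.fired is not None:
            extra = encoder.background_steps
        elif train_image_fn is conventional_train_image:
            extra = 0
        record.append(rec, rec.steps_used + extra)
        if progress_every and (k + 1) % progress_every == 0:
            print(f"  trained {k + 1}/{images.shape[0]} images, "
                  f"total steps {record.total_steps}")
    return record


def greedy_train_epoch(
    images,
    synapses: SynapseArray,
    lif_state: LifLayerState,
    encoder: EncoderConfig = EncoderConfig(),
    lif: LifConfig = LifConfig(),
    train: TrainConfig = TrainConfig(),
    seed: int = 0,
    progress_every: int | None = None,
) -> TrainRecord:
    """One pass over ``images`` in the given order, greedy mode."""
    return _train_epoch(greedy_train_image, images, synapses, lif_state,
                        encoder, lif, train, seed, progress_every)


def conventional_train_epoch(
    images,
    synapses: SynapseArray,
    lif_state: LifLayerState,
    encoder: EncoderConfig = EncoderConfig(),
    lif: LifConfig = LifConfig(),
    train: TrainConfig = TrainConfig(),
    seed: int = 0,
    progress_every: int | None = None,
) -> TrainRecord:
    """One pass over ``images`` with the conventional baseline."""
    return _train_epoch(conventional_train_image, images, synapses, lif_state,
                        encoder, lif, train, seed, progress_every)
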