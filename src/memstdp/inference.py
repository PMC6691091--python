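"""Static-mode inference: neuron labeling, prediction and evaluation.

After training, weights and thresholds are frozen.  The training images
are replayed once; for each image the first output neuron to fire earns a
confidence score of 1/(firing step, 1-based) for the image's true label —
earlier firing means a more confident match.  Each neuron is then assigned
the label with its highest accumulated score.  Prediction simply replays a
stimulus and reports the assigned label of the first neuron to fire.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .encoding import EncoderConfig, make_stimulus, sample_spikes
from .network import LifConfig, LifLayerState, lif_step

__all__ = [
    "UNASSIGNED",
    "ScoreTable",
    "label_neurons",
    "predict",
    "evaluate_accuracy",
    "pixel_error_rates",
]

#: reserved label for neurons that never fired during labeling
UNASSIGNED = -1


@dataclass
class ScoreTable:
    """Accumulated neuron-by-label confidence scores."""

    scores: np.ndarray  # (n_neurons, n_labels), >= 0

    @property
    def assigned_labels(self) -> np.ndarray:
        """argmax label per neuron (ties → lowest label); UNASSIGNED if silent."""
        labels = np.argmax(self.scores, axis=1)
        silent = ~np.any(self.scores > 0, axis=1)
        labels[silent] = UNASSIGNED
        return labels

    def __add__(self, other: "ScoreTable") -> "ScoreTable":
        return ScoreTable(self.scores + other.scores)


def _first_spike(
    weights: np.ndarray,
    thresholds: np.ndarray,
    stimulus,
    encoder: EncoderConfig,
    lif: LifConfig,
    rng: np.random.Generator,
    step_cap: int,
) -> tuple[int | None, int | None]:
    """Run a frozen network on one stimulus; (neuron, 1-based step) or Nones."""
    state = LifLayerState.create(weights.shape[1], lif)
    state.thresholds[:] = thresholds
    for t in range(1, step_cap + 1):
        spikes = sample_spikes(stimulus, rng)
        fired = lif_step(state, spikes, weights, lif, encoder.timestep,
                         step_index=t)
        if fired is not None:
            return fired, t
    return None, None


def label_neurons(
    weights: np.ndarray,
    thresholds: np.ndarray,
    images,
    labels,
    encoder: EncoderConfig = EncoderConfig(),
    lif: LifConfig = LifConfig(),
    seed: int = 0,
    n_labels: int | None = None,
    step_cap: int | None = None,
) -> ScoreTable:
    """Assign labels to output neurons by replaying labeled images.

    ``weights`` (n_inputs × n_neurons, μS) and per-neuron ``thresholds``
    stay frozen; lateral inhibition and the greedy stopping rule remain
    active.  The inference step cap defaults to the pattern phase cap; no
    background phase is used at inference.
    """
    images = np.asarray(images)
    labels = np.asarray(labels)
    if images.shape[0] != labels.shape[0]:
        raise ValueError("images and labels length mismatch")
    if n_labels is None:
        n_labels = int(labels.max()) + 1
    cap = step_cap or encoder.pattern_max_steps
    rng = substream(seed, "inference")
    scores = np.zeros((weights.shape[1], n_labels), dtype=float)
    for k in range(images.shape[0]):
        stim = make_stimulus(images[k], "pattern", encoder)
        neuron, t = _first_spike(weights, thresholds, stim, encoder, lif, rng, cap)
        if neuron is not None:
            scores[neuron, int(labels[k])] += 1.0 / t
    return ScoreTable(scores)


def predict(
    image,
    weights: np.ndarray,
    thresholds: np.ndarray,
    score_table: ScoreTable,
    encoder: EncoderConfig = EncoderConfig(),
    lif: LifConfig = LifConfig(),
    rng: np.random.Generator | None = None,
    seed: int = 0,
    step_cap: int | None = None,
) -> int | None:
    """Predicted label of ``image``: the first-firing neuron's label.

    Returns None when no neuron fires within the cap or the firing neuron
    is unassigned.
    """
    if rng is None:
        rng = substream(seed, "inference")
    cap = step_cap or encoder.pattern_max_steps
    stim = make_stimulus(image, "pattern", encoder)
    neuron, _t = _first_spike(weights, thresholds, stim, encoder, lif, rng, cap)
    if neuron is None:
        return None
    label = int(score_table.assigned_labels[neuron])
    return None if label == UNASSIGNED else label


def evaluate_accuracy(
    images,
    labels,
    weights: np.ndarray,
    thresholds: np.ndarray,
    score_table: ScoreTable,
    encoder: EncoderConfig = EncoderConfig(),
    lif: LifConfig = LifConfig(),
    seed: int = 0,
    step_cap: int | None = None,
) -> float:
    """Fraction of correctly predicted images (no-spike predictions count wrong)."""
    images = np.asarray(images)
    labels = np.asarray(labels)
    if images.shape[0] == 0:
        raise ValueError("empty evaluation set")
    rng = substream(seed, "inference")
    correct = 0
    for k in range(images.shape[0]):
        pred = predict(images[k], weights, thresholds, score_table, encoder,
                       lif, rng=rng, step_cap=step_cap)
        if pred is not None and pred == int(labels[k]):
            correct += 1
    return correct / images.shape[0]


def pixel_error_rates(
    weights_column: np.ndarray,
    target_image,
    w_min: float = 10.0,
    w_max: float = 50.0,
) -> tuple[float, float]:
    """Pattern/background pixel error rates of one neuron's receptive field.

    A target pixel is "pattern" iff its intensity is > 0; a synapse is
    "learned" iff its weight exceeds the midpoint (w_min + w_max)/2.
    pattern_error is the fraction of pattern pixels not learned and
    background_error the fraction of background pixels learned.  An
    undefined rate (no pixels of that kind) is reported as NaN.
    """
    w = np.asarray(weights_column, dtype=float).reshape(-1)
    target = np.asarray(target_image, dtype=float).reshape(-1)
    if w.shape != target.shape:
        raise ValueError("weight column and target image size mismatch")
    mid = 0.5 * (w_min + w_max)
    pattern = target > 0
    learned = w > mid
    n_pat = int(pattern.sum())
    n_bg = int((~pattern).sum())
    pattern_error = float(np.mean(~learned[pattern])) if n_pat else float("nan")
    background_error = float(np.mean(learned[~pattern])) if n_bg else float("nan")
    return pattern_error, background_error
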