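"""Weight-map visualization: per-neuron receptive fields as an image grid."""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["weight_map_grid"]


def weight_map_grid(weights: np.ndarray, side: int, n_cols: int = 10,
                    path=None):
    """Render each output neuron's weight column as a side×side heat map.

    ``weights`` is (n_inputs, n_outputs) with n_inputs == side².  Returns
    the Matplotlib figure; saves a PNG when ``path`` is given.
    """
    n_in, n_out = weights.shape
    if n_in != side * side:
        raise ValueError("weights rows must equal side**2")
    n_rows = math.ceil(n_out / n_cols)
    fig, axes = plt.subplots(n_rows, n_cols,
                             figsize=(1.2 * n_cols, 1.2 * n_rows))
    axes = np.atleast_1d(axes).reshape(n_rows, n_cols)
    vmin, vmax = float(weights.min()), float(weights.max())
    for j in range(n_rows * n_cols):
        ax = axes[j // n_cols, j % n_cols]
        ax.axis("off")
        if j < n_out:
            ax.imshow(weights[:, j].reshape(side, side), cmap="viridis",
                      vmin=vmin, vmax=vmax)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
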