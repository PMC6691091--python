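"""Synthetic pattern datasets and MNIST IDX-format I/O.

The synthetic generator emulates the statistics the encoder assumes: a
sparse set of bright "pattern" pixels on a dominant low-intensity
background, one fixed random template per class, per-sample truncated
Gaussian pixel noise.  It exists so the full pipeline (including the IDX
container) runs without downloading MNIST; the IDX reader handles the real
distribution files when they are present.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

from ._rng import substream

__all__ = [
    "SyntheticSpec",
    "generate_synthetic",
    "read_idx_images",
    "read_idx_labels",
    "write_idx",
]

_IDX_MAGIC_IMAGES = 0x00000803
_IDX_MAGIC_LABELS = 0x00000801


@dataclass(frozen=True)
class SyntheticSpec:
    """MNIST-like synthetic dataset parameters (defaults emulate MNIST scale)."""

    image_side: int = 28
    n_classes: int = 10
    pattern_pixel_fraction: float = 0.15
    foreground_intensity: int = 255
    background_intensity: int = 10
    pixel_noise_sd: float = 8.0
    samples_per_class: int = 100
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.pattern_pixel_fraction < 1:
            raise ValueError("pattern_pixel_fraction must lie in (0, 1)")
        if not (0 <= self.background_intensity < self.foreground_intensity <= 255):
            raise ValueError(
                "intensities must satisfy 0 <= background < foreground <= 255"
            )
        if self.image_side < 2 or self.n_classes < 1 or self.samples_per_class < 1:
            raise ValueError("degenerate dataset spec")
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel_noise_sd must be >= 0")


def class_templates(spec: SyntheticSpec) -> np.ndarray:
    """Fixed binary masks, one per class, with separability asserted.

    Each template marks round(fraction · side²) foreground pixels chosen
    uniformly.  Templates are resampled (bounded retries) until every pair
    differs in at least a quarter of the foreground pixel count.
    """
    n_pix = spec.image_side ** 2
    k = int(round(spec.pattern_pixel_fraction * n_pix))
    rng = substream(spec.seed, "templates")
    min_dist = max(1, k // 4)
    for _attempt in range(100):
        masks = np.zeros((spec.n_classes, n_pix), dtype=bool)
        for c in range(spec.n_classes):
            masks[c, rng.choice(n_pix, size=k, replace=False)] = True
        ok = True
        for a in range(spec.n_classes):
            for b in range(a + 1, spec.n_classes):
                if int(np.sum(masks[a] ^ masks[b])) < min_dist:
                    ok = False
        if ok:
            return masks.reshape(spec.n_classes, spec.image_side, spec.image_side)
    raise RuntimeError("could not generate separable class templates")


def generate_synthetic(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate (images, labels): uint8 images of shape (N, side, side).

    Samples are the class template scaled to foreground/background
    intensity plus truncated Gaussian noise, clipped to [0, 255]; no sample
    is ever all-zero (the template guarantees foreground pixels).
    """
    templates = class_templates(spec)
    rng = substream(spec.seed, "samples")
    n = spec.n_classes * spec.samples_per_class
    labels = np.repeat(np.arange(spec.n_classes), spec.samples_per_class)
    base = np.where(
        templates[labels],
        float(spec.foreground_intensity),
        float(spec.background_intensity),
    )
    if spec.pixel_noise_sd > 0:
        base = base + rng.normal(0.0, spec.pixel_noise_sd, size=base.shape)
    images = np.clip(np.rint(base), 0, 255).astype(np.uint8)
    # foreground must survive noise so normalization never degenerates
    flat = images.reshape(n, -1)
    assert np.all(flat.sum(axis=1) > 0)
    if spec.shuffle:
        order = substream(spec.seed, "order").permutation(n)
        images, labels = images[order], labels[order]
    return images, labels


# ---------------------------------------------------------------------------
# IDX (ubyte) container


def _read_header(f, expected_magic: int, kind: str) -> tuple[int, ...]:
    head = f.read(4)
    if len(head) < 4:
        raise ValueError(f"truncated IDX {kind} file: missing magic number")
    (magic,) = struct.unpack(">i", head)
    if magic != expected_magic:
        raise ValueError(
            f"bad IDX magic for {kind}: got 0x{magic:08x}, "
            f"expected 0x{expected_magic:08x}"
        )
    n_dims = magic & 0xFF
    dims = struct.unpack(f">{n_dims}i", f.read(4 * n_dims))
    return dims


def read_idx_images(path) -> np.ndarray:
    """Read an IDX3 image file → uint8 array of shape (N, rows, cols)."""
    with open(path, "rb") as f:
        n, rows, cols = _read_header(f, _IDX_MAGIC_IMAGES, "images")
        payload = np.frombuffer(f.read(), dtype=np.uint8)
    if payload.size != n * rows * cols:
        raise ValueError(
            f"IDX image payload has {payload.size} bytes, header promises "
            f"{n}x{rows}x{cols}"
        )
    return payload.reshape(n, rows, cols)


def read_idx_labels(path) -> np.ndarray:
    """Read an IDX1 label file → uint8 vector of length N."""
    with open(path, "rb") as f:
        (n,) = _read_header(f, _IDX_MAGIC_LABELS, "labels")
        payload = np.frombuffer(f.read(), dtype=np.uint8)
    if payload.size != n:
        raise ValueError(
            f"IDX label payload has {payload.size} bytes, header promises {n}"
        )
    return payload


def write_idx(path, array: np.ndarray) -> None:
    """Write a uint8 array as IDX: 3-D arrays → images, 1-D → labels."""
    arr = np.ascontiguousarray(array, dtype=np.uint8)
    if arr.ndim == 3:
        magic = _IDX_MAGIC_IMAGES
    elif arr.ndim == 1:
        magic = _IDX_MAGIC_LABELS
    else:
        raise ValueError("write_idx supports 1-D label or 3-D image arrays")
    with open(path, "wb") as f:
        f.write(struct.pack(">i", magic))
        f.write(struct.pack(f">{arr.ndim}i", *arr.shape))
        f.write(arr.tobytes())
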