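"""Patch sampling, intensity normalization and inference padding.

Training pairs follow the single-central-cell construction: the target is
the input patch multiplied by the mask of the instance touching the patch's
central pixel, and a configurable fraction of patches (default 20%) is
sampled with a background center so the model learns to emit empty images.

The "central pixel" of an even-sided patch is at 0-based index
``(patch_size // 2, patch_size // 2)``; every module in this package uses
that convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = [
    "TrainingPair",
    "normalize",
    "sample_training_pair",
    "pad_for_inference",
    "crop_padding",
]


@dataclass
class TrainingPair:
    input_patch: np.ndarray
    target_patch: np.ndarray
    has_center_cell: bool
    center: Tuple[int, int] = None  # (row, col) in unpadded image coordinates


def normalize(
    raw_image: np.ndarray, p_low: float = 0.1, p_high: float = 99.9
) -> np.ndarray:
    """Percentile-clip then min-max rescale an intensity image to [0, 1].

    Clipping at the (``p_low``, ``p_high``) percentiles makes the rescale
    robust to hot pixels common in fluorescence data. A constant image (zero
    percentile range) maps to all zeros.
    """
    raw_image = np.asarray(raw_image, dtype=np.float64)
    if raw_image.size == 0:
        raise ValueError("image must have at least one pixel")
    if not np.all(np.isfinite(raw_image)):
        raise ValueError("image contains non-finite pixels")
    lo, hi = np.percentile(raw_image, [p_low, p_high])
    if hi <= lo:
        return np.zeros_like(raw_image)
    return (np.clip(raw_image, lo, hi) - lo) / (hi - lo)


def pad_for_inference(
    image: np.ndarray, patch_size: int, mirror_px: int = 8
) -> np.ndarray:
    """Pad each side by ``patch_size // 2``: mirror-reflect the innermost
    ``mirror_px`` pixels, zero-fill the rest.

    With a 40-pixel patch this gives 20 pixels per side (8 mirror + 12 zero);
    with a 120-pixel patch, 60 per side.
    """
    if patch_size % 2 != 0:
        raise ValueError("patch_size must be even (half-size padding must be integral)")
    half = patch_size // 2
    if mirror_px > half:
        raise ValueError("mirror_px must be <= patch_size / 2")
    if mirror_px > min(image.shape[-2:]):
        raise ValueError("mirror_px exceeds image extent")
    pad_spec = [(0, 0)] * (image.ndim - 2) + [(mirror_px, mirror_px)] * 2
    out = np.pad(image, pad_spec, mode="reflect") if mirror_px else np.asarray(image)
    zero = half - mirror_px
    pad_spec = [(0, 0)] * (image.ndim - 2) + [(zero, zero)] * 2
    return np.pad(out, pad_spec, mode="constant")


def crop_padding(padded: np.ndarray, patch_size: int) -> np.ndarray:
    """Inverse of :func:`pad_for_inference` (bit-exact on the interior)."""
    half = patch_size // 2
    return padded[..., half:-half, half:-half]


def extract_patch(
    padded: np.ndarray, point: Tuple[int, int], patch_size: int
) -> np.ndarray:
    """Window of side ``patch_size`` whose central pixel sits at ``point``
    (padded coordinates)."""
    h = patch_size // 2
    r, c = int(point[0]), int(point[1])
    if (r - h < 0 or c - h < 0
            or r - h + patch_size > padded.shape[-2]
            or c - h + patch_size > padded.shape[-1]):
        raise ValueError(f"patch window at {(r, c)} exceeds image bounds")
    return padded[..., r - h: r - h + patch_size, c - h: c - h + patch_size]


def sample_training_pair(
    scene,
    patch_size: int,
    p_center: float = 0.8,
    rng: np.random.Generator | None = None,
    mirror_px: int = 8,
) -> TrainingPair:
    """Draw one (input patch, single-central-cell target) pair from a scene.

    With probability ``p_center`` the patch center lands uniformly on a
    foreground pixel, otherwise uniformly on a background pixel. The target
    is ``input * (labels == labels[center])`` for a foreground center and
    all zeros for a background center.
    """
    if not 0.0 <= p_center <= 1.0:
        raise ValueError("p_center must be in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng

    image = scene.image if scene.image.ndim == 2 else scene.image[-1]
    labels = scene.labels
    padded_img = pad_for_inference(image, patch_size, mirror_px)
    padded_lab = pad_for_inference(
        labels.astype(np.float64), patch_size, mirror_px
    ).round().astype(np.int64)

    want_fg = bool(rng.random() < p_center)
    stratum = labels != 0 if want_fg else labels == 0
    n = int(stratum.sum())
    if n == 0:
        raise ValueError(
            f"scene has no {'foreground' if want_fg else 'background'} pixels"
        )
    flat = rng.integers(n)
    rows, cols = np.nonzero(stratum)
    r, c = int(rows[flat]), int(cols[flat])

    half = patch_size // 2
    point = (r + half, c + half)  # padded coordinates
    input_patch = extract_patch(padded_img, point, patch_size)
    lab_patch = extract_patch(padded_lab, point, patch_size)
    center_label = lab_patch[half, half]
    if center_label == 0:
        target = np.zeros_like(input_patch)
        has_cell = False
    else:
        target = input_patch * (lab_patch == center_label)
        has_cell = True
    return TrainingPair(
        input_patch=np.ascontiguousarray(input_patch),
        target_patch=target,
        has_center_cell=has_cell,
        center=(r, c),
    )
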