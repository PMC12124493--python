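"""From accepted object predictions to an instance segmentation.

Predicted single-cell intensity images are binarized at a brightness
threshold of 10% of the input image's mean intensity, small masks are
discarded (fewer than 20 pixels by default; a per-channel rule for
two-channel cytoplasm+nucleus data), and surviving masks are flattened into
an integer label map, resolving overlaps by highest predicted intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .engine import ObjectPrediction

__all__ = ["InstanceMasks", "binarize_objects", "filter_masks", "assign_instances"]

logger = logging.getLogger(__name__)


@dataclass
class InstanceMasks:
    """Binary masks in unpadded full-image coordinates, with the predicted
    intensities behind them (used to resolve overlaps)."""

    shape: Tuple[int, int]
    masks: List[np.ndarray] = field(default_factory=list)
    intensities: List[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.masks)


def binarize_objects(
    objects: Sequence[ObjectPrediction],
    image: np.ndarray,
    threshold_frac: float = 0.1,
    patch_size: Optional[int] = None,
    mode: str = "patch",
) -> InstanceMasks:
    """Binary mask per object at ``threshold_frac`` x mean(image).

    ``image`` is the normalized, unpadded input micrograph; object anchors
    are padded coordinates, shifted back by ``patch_size // 2`` here. Pixels
    falling outside the image are dropped. The comparison is ``>= t``.

    ``mode="patch"`` thresholds each object's raw predicted intensities.
    ``mode="contribution"`` replays the accepted objects in order and
    thresholds only the intensity each one newly added to the internal
    image (``max(patch - P, 0)`` under the max merge rule). With an
    imperfect predictor, a cell can be accepted a second time to fill in
    the thin residual ring the first prediction missed; its contribution
    is just that ring, so the minimum-size filter then removes the
    duplicate, whereas its raw patch is a second full-cell mask. For
    predictions that are first at their location the two modes coincide.
    """
    if threshold_frac <= 0:
        raise ValueError("threshold_frac must be > 0")
    if mode not in ("patch", "contribution"):
        raise ValueError("mode must be 'patch' or 'contribution'")
    img2d = image if image.ndim == 2 else image[-1]
    t = threshold_frac * float(np.mean(image))
    h, w = img2d.shape
    out = InstanceMasks(shape=(h, w))
    internal = None
    for obj in objects:
        ps = obj.patch.shape[0] if patch_size is None else patch_size
        half = ps // 2
        if mode == "contribution":
            if internal is None:
                internal = np.zeros((h + ps, w + ps))
            fp = (slice(obj.anchor[0] - half, obj.anchor[0] - half + ps),
                  slice(obj.anchor[1] - half, obj.anchor[1] - half + ps))
            values = np.clip(obj.patch - internal[fp], 0.0, None)
            internal[fp] = np.maximum(internal[fp], obj.patch)
        else:
            values = obj.patch
        r0 = obj.anchor[0] - half - half  # unpad shift then footprint corner
        c0 = obj.anchor[1] - half - half
        mask = np.zeros((h, w), dtype=bool)
        inten = np.zeros((h, w), dtype=np.float64)
        rs, cs = max(r0, 0), max(c0, 0)
        re, ce = min(r0 + ps, h), min(c0 + ps, w)
        if rs < re and cs < ce:
            patch = values[rs - r0: re - r0, cs - c0: ce - c0]
            mask[rs:re, cs:ce] = patch >= t
            inten[rs:re, cs:ce] = np.where(patch >= t, patch, 0.0)
        out.masks.append(mask)
        out.intensities.append(inten)
    return out


def filter_masks(
    masks: InstanceMasks,
    min_pixels: int = 20,
    channel_images: Optional[np.ndarray] = None,
    channel_min_pixels: Tuple[int, int] = (1, 20),
    threshold_frac: float = 0.1,
) -> InstanceMasks:
    """Drop masks that are too small to be real cells.

    Single-channel rule: strictly fewer than ``min_pixels`` pixels. When a
    two-channel image ``(2, H, W)`` is given (channel 0 cytoplasm, channel 1
    nucleus), a mask is dropped if its count of thresholded channel-1 pixels
    is below ``channel_min_pixels[1]`` (default 20) or its count of
    thresholded channel-0 pixels is below ``channel_min_pixels[0]``
    (default 1); per-channel thresholds are ``threshold_frac`` x the
    channel mean.
    """
    if min_pixels < 0:
        raise ValueError("min_pixels must be >= 0")
    out = InstanceMasks(shape=masks.shape)
    if channel_images is not None:
        chan_fg = [
            ch >= threshold_frac * float(ch.mean()) for ch in channel_images
        ]
    for mask, inten in zip(masks.masks, masks.intensities):
        if channel_images is None:
            keep = int(mask.sum()) >= min_pixels
        else:
            counts = [int((mask & fg).sum()) for fg in chan_fg]
            keep = all(c >= m for c, m in zip(counts, channel_min_pixels))
        if keep:
            out.masks.append(mask)
            out.intensities.append(inten)
    return out


def assign_instances(masks: InstanceMasks, min_pixels: int = 0) -> np.ndarray:
    """Flatten possibly-overlapping masks into an integer label map.

    Contested pixels go to the mask with the highest predicted intensity
    there (ties: lower mask index). A mask that loses every pixel — or,
    when ``min_pixels`` > 0, is reduced below that size — is dropped with a
    warning, and labels are renumbered 1..n densely.
    """
    h, w = masks.shape
    labels = np.zeros((h, w), dtype=np.int32)
    if not masks.masks:
        return labels
    best = np.full((h, w), -np.inf)
    for i, (mask, inten) in enumerate(zip(masks.masks, masks.intensities), start=1):
        win = mask & (inten > best)  # strict: ties stay with the lower index
        labels[win] = i
        best[win] = inten[win]
    counts = np.bincount(labels.ravel(), minlength=len(masks.masks) + 1)
    keep = np.nonzero(counts[1:] >= max(min_pixels, 1))[0] + 1
    lost = set(range(1, len(masks.masks) + 1)) - set(int(v) for v in keep)
    for i in sorted(lost):
        level = logging.WARNING if counts[i] == 0 else logging.DEBUG
        logger.log(
            level, "mask %d kept %d pixels after overlap resolution; dropped",
            i, int(counts[i]),
        )
        labels[labels == i] = 0
    remap = np.zeros(len(masks.masks) + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    return remap[labels]
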