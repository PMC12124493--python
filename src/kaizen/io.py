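"""Image readers/writers and run manifests.

TIFF is the preferred interchange format (float32 micrographs, uint16 label
maps); 8/16-bit PNG is accepted for input. Intensities are returned as raw
floats — normalization is a separate, explicit step.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "read_image",
    "read_labels",
    "write_image",
    "write_labels",
    "write_manifest",
    "export_training_pairs",
    "export_objects",
]

PathLike = Union[str, Path]
_SUFFIXES = {".tif", ".tiff", ".png"}


def _read_array(path: PathLike) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() not in _SUFFIXES:
        raise ValueError(f"unsupported image format: {path.suffix!r} (TIFF or PNG)")
    if path.suffix.lower() == ".png":
        return np.asarray(iio.imread(path))
    return np.asarray(tifffile.imread(path))


def read_image(path: PathLike, channels: int = 1) -> np.ndarray:
    """Load a micrograph as float intensities (no normalization applied)."""
    arr = _read_array(path)
    if channels == 1:
        if arr.ndim == 3:
            raise ValueError(
                f"{path}: got a {arr.shape} multi-channel image in "
                "single-channel mode"
            )
    elif arr.ndim == 3 and arr.shape[-1] in (2, 3, 4) and arr.shape[0] not in (2, 3, 4):
        arr = np.moveaxis(arr, -1, 0)  # HWC -> CHW
    if not np.issubdtype(arr.dtype, np.floating) and not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}")
    return arr.astype(np.float64)


def read_labels(path: PathLike) -> np.ndarray:
    """Load an integer instance label map (0 = background)."""
    arr = _read_array(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: label maps must be 2-D, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.floating):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError(f"{path}: non-integer values in label map")
        arr = np.round(arr)
    return arr.astype(np.int32)


def write_image(path: PathLike, image: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(image, dtype=np.float32))


def write_labels(path: PathLike, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels out of uint16 range")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def write_manifest(path: PathLike, manifest: dict) -> None:
    """Persist the run configuration/seed record as JSON."""
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def export_training_pairs(pairs, path: PathLike) -> None:
    """Write (input, target) pairs as an interleaved multi-page float TIFF
    for visual inspection: page 2k is input k, page 2k+1 its target."""
    stack = []
    for pair in pairs:
        stack.append(np.asarray(pair.input_patch, dtype=np.float32))
        stack.append(np.asarray(pair.target_patch, dtype=np.float32))
    tifffile.imwrite(Path(path), np.stack(stack))


def export_objects(objects, path: PathLike, patch_size: int) -> None:
    """Write accepted object patches as a multi-page float TIFF plus a
    CSV sidecar (same stem) of anchors (unpadded coordinates) and passes."""
    path = Path(path)
    half = patch_size // 2
    if objects:
        tifffile.imwrite(
            path, np.stack([o.patch.astype(np.float32) for o in objects])
        )
    rows = ["index,row,col,source_pass,accepted"]
    for i, o in enumerate(objects):
        rows.append(f"{i},{o.anchor[0] - half},{o.anchor[1] - half},"
                    f"{o.source_pass},{int(o.accepted)}")
    path.with_suffix(".csv").write_text("\n".join(rows) + "\n")
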