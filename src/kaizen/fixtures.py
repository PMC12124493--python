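"""Synthetic fluorescence micrographs with ground-truth instance labels.

The generator emulates nuclei-style fluorescence data: bright elliptical
cells with a radially decaying intensity profile on a dark, optionally noisy
background, together with an integer label map (0 = background). It also
provides :class:`OraclePredictor`, a ground-truth-backed stand-in for a
trained single-cell predictor, which lets the decomposition engine be tested
independently of model quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .patches import pad_for_inference

__all__ = ["SceneParams", "Scene", "generate_scene", "OraclePredictor"]


@dataclass
class SceneParams:
    """Parameters of one synthetic scene.

    ``min_center_separation`` defaults to twice the maximum radius plus two
    pixels, which guarantees non-overlapping cells; pass a smaller value
    (``touching=True`` convenience) to allow near-touching cells.
    """

    height: int = 128
    width: int = 128
    n_cells: int = 10
    radius_range: Tuple[float, float] = (4.5, 9.0)
    axis_ratio_range: Tuple[float, float] = (0.6, 1.0)
    intensity_range: Tuple[float, float] = (0.5, 1.0)
    background_noise_sd: float = 0.02
    min_center_separation: Optional[float] = None
    touching: bool = False
    # keep cells this far clear of the frame edge (in addition to their
    # radius) so the inference-time mirror band reflects only background;
    # reflection excludes the edge pixel, so the band reads one pixel
    # deeper than its 8-pixel width. Set to 0 to allow border cells.
    border_clearance: float = 9.0
    channels: int = 1
    cytoplasm_scale: float = 1.6
    cytoplasm_intensity: float = 0.4
    seed: int = 0
    max_attempts_per_cell: int = 2000

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("height and width must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("radius_range", "axis_ratio_range", "intensity_range"):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise ValueError(f"{name} must be a non-empty interval")
        if self.channels not in (1, 2):
            raise ValueError("channels must be 1 or 2")
        if self.min_center_separation is None:
            # non-overlap default; "touching" scenes allow adjacency
            rmax = self.radius_range[1]
            self.min_center_separation = (
                1.2 * rmax if self.touching else 2.0 * rmax + 2.0
            )
        if self.min_center_separation < 0:
            raise ValueError("min_center_separation must be >= 0")


@dataclass
class Scene:
    """A micrograph plus its ground-truth instance label map."""

    image: np.ndarray  # (H, W) or (C, H, W), float in [0, 1]
    labels: np.ndarray  # (H, W) int, 0 = background
    params: SceneParams = field(repr=False, default=None)

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())


def _ellipse_profile(
    shape: Tuple[int, int],
    center: Tuple[float, float],
    radius: float,
    axis_ratio: float,
    angle: float,
    peak: float,
    scale: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Radially decaying rotated ellipse: peak at center, 50% at the rim.

    Returns (intensity image, boolean mask).
    """
    h, w = shape
    a = radius * scale
    b = radius * axis_ratio * scale
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    rho2 = (u / a) ** 2 + (v / b) ** 2
    mask = rho2 <= 1.0
    img = np.zeros(shape, dtype=np.float64)
    img[mask] = peak * (1.0 - 0.5 * rho2[mask])
    return img, mask


def generate_scene(params: SceneParams) -> Scene:
    """Render a synthetic micrograph and its label map.

    Cell centers are rejection-sampled so that all pairwise distances are at
    least ``min_center_separation`` and every cell fits inside the frame.
    Deterministic for a fixed ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width

    centers: list[Tuple[float, float]] = []
    cells = []
    for _ in range(params.n_cells):
        placed = False
        for _attempt in range(params.max_attempts_per_cell):
            radius = rng.uniform(*params.radius_range)
            margin = radius * (
                params.cytoplasm_scale if params.channels == 2 else 1.0
            ) + params.border_clearance
            if h - 2 * margin <= 0 or w - 2 * margin <= 0:
                continue
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            if all(
                np.hypot(cy - oy, cx - ox) >= params.min_center_separation
                for oy, ox in centers
            ):
                centers.append((cy, cx))
                cells.append(
                    dict(
                        center=(cy, cx),
                        radius=radius,
                        axis_ratio=rng.uniform(*params.axis_ratio_range),
                        angle=rng.uniform(0.0, np.pi),
                        peak=rng.uniform(*params.intensity_range),
                    )
                )
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place {params.n_cells} cells with separation "
                f"{params.min_center_separation:.1f} in a {h}x{w} frame "
                f"after {params.max_attempts_per_cell} attempts each"
            )

    nucleus = np.zeros((h, w), dtype=np.float64)
    labels = np.zeros((h, w), dtype=np.int32)
    cyto = np.zeros((h, w), dtype=np.float64) if params.channels == 2 else None
    for idx, cell in enumerate(cells, start=1):
        img, mask = _ellipse_profile(
            (h, w), cell["center"], cell["radius"], cell["axis_ratio"],
            cell["angle"], cell["peak"],
        )
        nucleus = np.maximum(nucleus, img)
        labels[mask] = idx
        if cyto is not None:
            cimg, _ = _ellipse_profile(
                (h, w), cell["center"], cell["radius"], cell["axis_ratio"],
                cell["angle"], params.cytoplasm_intensity * cell["peak"],
                scale=params.cytoplasm_scale,
            )
            cyto = np.maximum(cyto, cimg)

    def _noisy(chan: np.ndarray) -> np.ndarray:
        if params.background_noise_sd > 0:
            chan = chan + rng.normal(0.0, params.background_noise_sd, size=chan.shape)
        return np.clip(chan, 0.0, 1.0)

    if params.channels == 2:
        image = np.stack([_noisy(cyto), _noisy(nucleus)])
    else:
        image = _noisy(nucleus)
    return Scene(image=image.astype(np.float64), labels=labels, params=params)


class OraclePredictor:
    """Ground-truth single-cell predictor.

    ``predict(point, image)`` returns the patch of the scene image multiplied
    by the mask of the instance whose label occupies the patch's central
    pixel, or an all-zero patch when that pixel is background — exactly the
    target a perfectly trained model would emit. The scene is padded with the
    same mirror+zero scheme as the inference input so padded coordinates line
    up.
    """

    def __init__(self, scene: Scene, patch_size: int, mirror_px: int = 8):
        self.patch_size = int(patch_size)
        self.half = self.patch_size // 2
        img = scene.image if scene.image.ndim == 2 else scene.image[-1]
        self.image = pad_for_inference(img, self.patch_size, mirror_px)
        self.labels = pad_for_inference(
            scene.labels.astype(np.float64), self.patch_size, mirror_px,
        ).round().astype(np.int32)

    def predict(self, point: Tuple[int, int], image: Optional[np.ndarray] = None) -> np.ndarray:
        r, c = int(point[0]), int(point[1])
        h = self.half
        ps = self.patch_size
        if (r - h < 0 or c - h < 0
                or r - h + ps > self.image.shape[0]
                or c - h + ps > self.image.shape[1]):
            raise ValueError(f"patch window at {point} exceeds padded image bounds")
        win_img = self.image[r - h: r - h + ps, c - h: c - h + ps]
        win_lab = self.labels[r - h: r - h + ps, c - h: c - h + ps]
        center_label = win_lab[h, h]
        if center_label == 0:
            return np.zeros((ps, ps), dtype=np.float64)
        return win_img * (win_lab == center_label)
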