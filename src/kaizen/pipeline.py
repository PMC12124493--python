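"""End-to-end segmentation: normalize -> pad -> decompose -> masks -> labels.

:class:`KaizenSegmenter` is the scikit-learn-style front door: construct
with hyperparameters, ``fit`` on images with ground-truth label maps (which
trains the single-cell predictor on sampled patch pairs), ``predict`` on new
images to get instance label maps. :func:`segment_image` is the stateless
core used both by the estimator and by oracle-driven tests.
"""

from __future__ import annotations

from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .engine import EngineConfig, InternalState, kaizen_multipass
from .evalap import evaluate_set
from .fixtures import Scene
from .patches import normalize, sample_training_pair, TrainingPair
from .postseg import assign_instances, binarize_objects, filter_masks
from .vqvae import VQVAE, VQVAEConfig

__all__ = ["PROFILES", "KaizenSegmenter", "segment_image", "training_pair_stream"]

# Reference dataset profiles: nuclei-only (BBBC039-style) and whole-cell
# (neuroblastoma-style) settings, plus the small configuration used
# throughout the tests.
PROFILES = {
    "u2os": dict(patch_size=40, n_points=10, max_iter=30,
                 codebook_size=128, train_steps=500_000),
    "neuroblastoma": dict(patch_size=120, n_points=1, max_iter=100,
                          codebook_size=128, train_steps=500_000),
    "toy": dict(patch_size=32, n_points=10, max_iter=30,
                codebook_size=32, train_steps=3000),
}


def training_pair_stream(
    scenes: Sequence[Scene],
    patch_size: int,
    p_center: float = 0.8,
    rng: Optional[np.random.Generator] = None,
    mirror_px: int = 8,
) -> Iterator[TrainingPair]:
    """Endless stream of training pairs drawn from a pool of scenes."""
    rng = np.random.default_rng() if rng is None else rng
    while True:
        scene = scenes[rng.integers(len(scenes))]
        yield sample_training_pair(scene, patch_size, p_center, rng, mirror_px)


def segment_image(
    image: np.ndarray,
    predictor,
    engine_config: EngineConfig,
    threshold_frac: float = 0.1,
    min_pixels: int = 20,
    channel_images: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, InternalState]:
    """Decompose one normalized, unpadded micrograph into a label map."""
    state = kaizen_multipass(image, predictor, engine_config)
    masks = binarize_objects(state.objects, image, threshold_frac,
                             patch_size=engine_config.patch_size,
                             mode="contribution")
    masks = filter_masks(masks, min_pixels=min_pixels,
                         channel_images=channel_images,
                         threshold_frac=threshold_frac)
    return assign_instances(masks, min_pixels=min_pixels), state


class KaizenSegmenter(BaseEstimator):
    """Trainable cell-instance segmenter.

    Parameters default to the ``"toy"`` profile; pass ``profile="u2os"`` or
    ``"neuroblastoma"`` for the full-scale reference settings. Any explicit
    keyword overrides its profile value.

    Fitted attributes: ``model_`` (the trained single-cell predictor) and
    ``engine_config_``.
    """

    def __init__(
        self,
        profile: str = "toy",
        patch_size: Optional[int] = None,
        n_points: Optional[int] = None,
        max_iter: Optional[int] = None,
        codebook_size: Optional[int] = None,
        embedding_dim: int = 2,
        train_steps: Optional[int] = None,
        p_center: float = 0.8,
        threshold_frac: float = 0.1,
        min_pixels: int = 20,
        max_passes: int = 10,
        mirror_px: int = 8,
        normalize_inputs: bool = True,
        seed: int = 0,
    ):
        self.profile = profile
        self.patch_size = patch_size
        self.n_points = n_points
        self.max_iter = max_iter
        self.codebook_size = codebook_size
        self.embedding_dim = embedding_dim
        self.train_steps = train_steps
        self.p_center = p_center
        self.threshold_frac = threshold_frac
        self.min_pixels = min_pixels
        self.max_passes = max_passes
        self.mirror_px = mirror_px
        self.normalize_inputs = normalize_inputs
        self.seed = seed

    # -- config resolution -------------------------------------------------

    def _resolved(self, key: str):
        value = getattr(self, key)
        if value is not None:
            return value
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        return PROFILES[self.profile][key]

    def _vqvae_config(self) -> VQVAEConfig:
        patch_size = self._resolved("patch_size")
        if self.profile == "toy" or patch_size <= 32:
            base = VQVAEConfig.toy(
                patch_size=patch_size,
                codebook_size=self._resolved("codebook_size"),
                embedding_dim=self.embedding_dim,
                train_steps=self._resolved("train_steps"),
                seed=self.seed,
            )
            return base
        return VQVAEConfig(
            patch_size=patch_size,
            codebook_size=self._resolved("codebook_size"),
            embedding_dim=self.embedding_dim,
            train_steps=self._resolved("train_steps"),
            seed=self.seed,
        )

    def _engine_config(self) -> EngineConfig:
        return EngineConfig(
            patch_size=self._resolved("patch_size"),
            n_points=self._resolved("n_points"),
            max_iter=self._resolved("max_iter"),
            max_passes=self.max_passes,
            mirror_px=self.mirror_px,
        )

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y=None, steps: Optional[int] = None) -> "KaizenSegmenter":
        """Train the single-cell predictor.

        ``X``: sequence of intensity images (or :class:`Scene` objects, in
        which case ``y`` may be omitted); ``y``: matching instance label
        maps.
        """
        scenes = self._as_scenes(X, y)
        cfg = self._vqvae_config()
        rng = np.random.default_rng(self.seed + 1)
        stream = training_pair_stream(
            scenes, cfg.patch_size, self.p_center, rng, self.mirror_px
        )
        self.model_ = VQVAE(cfg).fit(stream, steps=steps)
        self.engine_config_ = self._engine_config()
        return self

    def predict(self, X) -> List[np.ndarray]:
        """Instance label map for each input image."""
        if not hasattr(self, "model_"):
            raise RuntimeError("KaizenSegmenter is not fitted")
        out = []
        for image in X:
            image = self._as_image(image)
            labels, _ = segment_image(
                image, self.model_, self.engine_config_,
                self.threshold_frac, self.min_pixels,
            )
            out.append(labels)
        return out

    def score(self, X, y, tau: float = 0.5) -> float:
        """Mean AP at threshold ``tau`` against ground-truth label maps."""
        preds = self.predict(X)
        truths = [s.labels if isinstance(s, Scene) else np.asarray(s) for s in y]
        table = evaluate_set(preds, truths, taus=(tau,))
        return float(table.loc["mean", tau])

    # -- helpers -----------------------------------------------------------

    def _as_image(self, x) -> np.ndarray:
        img = x.image if isinstance(x, Scene) else np.asarray(x, dtype=np.float64)
        if img.ndim == 3:
            img = img[-1]
        return normalize(img) if self.normalize_inputs else img

    def _as_scenes(self, X, y) -> List[Scene]:
        if y is None:
            scenes = list(X)
            if not all(isinstance(s, Scene) for s in scenes):
                raise ValueError("without y, X must be a sequence of Scene objects")
            return scenes
        scenes = []
        for img, lab in zip(X, y):
            img = np.asarray(img, dtype=np.float64)
            if self.normalize_inputs:
                img = normalize(img) if img.ndim == 2 else np.stack(
                    [normalize(c) for c in img]
                )
            scenes.append(Scene(image=img, labels=np.asarray(lab)))
        return scenes
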