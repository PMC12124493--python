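"""Iterative error-driven image decomposition.

The engine keeps an internal predicted image ``P`` (the merge of every
accepted single-cell prediction) next to the external input ``I``, derives
the error image ``E = I - P``, proposes prediction points where a 7x7
box-sum of ``E`` peaks (suppressing a 32x32 region around each chosen point
before picking the next), asks the predictor for a single-cell hypothesis at
each point, and keeps a hypothesis only when merging it strictly lowers the
global mean absolute error. Passes repeat on the residual error image so
cells masked by earlier mistakes get a second chance.

All coordinates here are (row, col) in the padded image domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Protocol, Tuple

import numpy as np
from scipy.signal import convolve2d

from .patches import crop_padding, pad_for_inference

__all__ = [
    "EngineConfig",
    "ObjectPrediction",
    "InternalState",
    "merge",
    "propose_points",
    "try_accept",
    "kaizen_pass",
    "kaizen_multipass",
]

logger = logging.getLogger(__name__)


class Predictor(Protocol):
    patch_size: int

    def predict(self, point: Tuple[int, int], image: np.ndarray) -> np.ndarray: ...


@dataclass
class EngineConfig:
    """Inference loop settings.

    ``n_points`` simultaneous proposals per iteration and ``max_iter``
    iterations per pass (reference values: 10/30 for nuclei-only data, 1/100
    for whole-cell data); a 7x7 ones kernel scores proposal locations and a
    32x32 window around each accepted proposal is zeroed before the next one
    is drawn.
    """

    patch_size: int = 40
    n_points: int = 10
    max_iter: int = 30
    proposal_kernel: int = 7
    suppression_window: int = 32
    min_improvement: float = 0.0
    max_passes: int = 10
    mirror_px: int = 8
    merge_rule: str = "max"  # or "add"

    def __post_init__(self) -> None:
        if self.n_points < 1 or self.max_iter < 1 or self.max_passes < 1:
            raise ValueError("n_points, max_iter and max_passes must be >= 1")
        if self.min_improvement < 0:
            raise ValueError("min_improvement must be >= 0")
        if self.merge_rule not in ("max", "add"):
            raise ValueError("merge_rule must be 'max' or 'add'")


@dataclass
class ObjectPrediction:
    """A patch-sized single-cell intensity image anchored at ``anchor``
    (padded coordinates of the patch's central pixel)."""

    patch: np.ndarray
    anchor: Tuple[int, int]
    source_pass: int = 1
    accepted: bool = False

    def footprint(self, patch_size: Optional[int] = None) -> Tuple[slice, slice]:
        ps = self.patch.shape[0] if patch_size is None else patch_size
        h = ps // 2
        r, c = self.anchor
        return slice(r - h, r - h + ps), slice(c - h, c - h + ps)


@dataclass
class InternalState:
    """Input image, internal prediction, error image and accepted objects."""

    input: np.ndarray
    internal: np.ndarray = None
    error: np.ndarray = None
    objects: List[ObjectPrediction] = field(default_factory=list)
    loss: float = None

    def __post_init__(self) -> None:
        if self.internal is None:
            self.internal = np.zeros_like(self.input)
        if self.error is None:
            self.error = self.input - self.internal
        if self.loss is None:
            self.loss = float(np.mean(np.abs(self.error)))


def merge(internal: np.ndarray, prediction: ObjectPrediction,
          rule: str = "max") -> np.ndarray:
    """Composite a prediction into the internal image (new array).

    The default pointwise-max rule is idempotent, so re-predicting an
    already-explained cell can never look like an improvement; the additive
    rule is available for overlap-heavy data.
    """
    rows, cols = prediction.footprint()
    if (rows.start < 0 or cols.start < 0
            or rows.stop > internal.shape[0] or cols.stop > internal.shape[1]):
        raise ValueError(f"prediction footprint {rows, cols} out of bounds")
    out = internal.copy()
    if rule == "max":
        out[rows, cols] = np.maximum(out[rows, cols], prediction.patch)
    else:
        out[rows, cols] = out[rows, cols] + prediction.patch
    return out


def propose_points(error: np.ndarray, n_points: int, kernel: int = 7,
                   suppression: int = 32,
                   valid_margin: int = 0) -> List[Tuple[int, int]]:
    """Up to ``n_points`` locations of descending 7x7 box-sum of the error.

    The box-sum map is computed once ("same" size, zero boundary); after
    each pick, the ``suppression`` x ``suppression`` window centered on it
    (rows/cols ``[p - s//2, p + (s+1)//2)``, clipped at borders) is zeroed in
    the working map. Locations whose box-sum is <= 0 are never proposed, so
    the list may be shorter than ``n_points``. Ties break to the smallest
    row-major index.
    """
    if not np.all(np.isfinite(error)):
        raise ValueError("error image contains non-finite values")
    score = convolve2d(error, np.ones((kernel, kernel)), mode="same")
    lo = suppression // 2
    hi = suppression - lo
    m = valid_margin
    points: List[Tuple[int, int]] = []
    for _ in range(n_points):
        flat = int(np.argmax(score))  # first (row-major smallest) maximum
        r, c = np.unravel_index(flat, score.shape)
        if score[r, c] <= 0:
            break
        # a maximum in the padded border is served by the nearest anchor
        # whose patch window still fits (and still covers the maximum)
        pr = int(np.clip(r, m, score.shape[0] - m))
        pc = int(np.clip(c, m, score.shape[1] - m))
        if (pr, pc) not in points:
            points.append((pr, pc))
        score[max(r - lo, 0): r + hi, max(c - lo, 0): c + hi] = 0.0
    return points


def _footprint_loss_delta(state: InternalState, prediction: ObjectPrediction,
                          rule: str) -> Tuple[float, np.ndarray]:
    """Change in global mean |I - P| from merging, evaluated only over the
    prediction's footprint (pixels elsewhere are unchanged)."""
    rows, cols = prediction.footprint()
    i_win = state.input[rows, cols]
    p_win = state.internal[rows, cols]
    if rule == "max":
        p_new = np.maximum(p_win, prediction.patch)
    else:
        p_new = p_win + prediction.patch
    delta = (np.abs(i_win - p_new).sum() - np.abs(i_win - p_win).sum()) / state.input.size
    return float(delta), p_new


def try_accept(state: InternalState, prediction: ObjectPrediction,
               min_improvement: float = 0.0, rule: str = "max") -> bool:
    """Accept ``prediction`` iff it strictly lowers the global L1 loss by
    more than ``min_improvement``; mutates ``state`` on acceptance."""
    delta, p_new = _footprint_loss_delta(state, prediction, rule)
    if delta < -min_improvement:
        rows, cols = prediction.footprint()
        state.internal[rows, cols] = p_new
        state.error[rows, cols] = state.input[rows, cols] - p_new
        state.loss = max(state.loss + delta, 0.0)  # guard float round-off
        prediction.accepted = True
        state.objects.append(prediction)
        return True
    return False


def kaizen_pass(image: np.ndarray, predictor: Predictor, config: EngineConfig,
                state: Optional[InternalState] = None,
                source_pass: int = 1) -> InternalState:
    """One pass of the core loop on a padded image.

    ``image`` is what the predictor sees; ``state`` (default: a fresh state
    whose input is ``image`` itself) is what acceptance is judged against.
    Iterates propose -> predict -> accept until an iteration accepts nothing
    or ``max_iter`` is reached.
    """
    if state is None:
        state = InternalState(input=np.asarray(image, dtype=np.float64))
    for iteration in range(config.max_iter):
        points = propose_points(
            state.error, config.n_points,
            config.proposal_kernel, config.suppression_window,
            valid_margin=config.patch_size // 2,
        )
        accepted_this_iter = 0
        for point in points:
            try:
                patch = predictor.predict(point, image)
            except Exception as exc:
                raise RuntimeError(f"predictor failed at point {point}") from exc
            pred = ObjectPrediction(
                patch=np.asarray(patch, dtype=np.float64),
                anchor=point, source_pass=source_pass,
            )
            if try_accept(state, pred, config.min_improvement, config.merge_rule):
                accepted_this_iter += 1
        logger.debug(
            "pass %d iter %d: %d proposed, %d accepted, loss %.6g",
            source_pass, iteration + 1, len(points), accepted_this_iter, state.loss,
        )
        if accepted_this_iter == 0:
            break
    return state


def kaizen_multipass(image: np.ndarray, predictor: Predictor,
                     config: EngineConfig) -> InternalState:
    """Full inference on an unpadded micrograph.

    Pass 1 runs on the padded input; each later pass feeds the predictor the
    previous residual error (clamped to >= 0, re-padded) while acceptance is
    still judged against the original input, so the global loss is
    monotonically non-increasing. Stops when a pass accepts nothing or after
    ``max_passes`` passes.
    """
    padded = pad_for_inference(
        np.asarray(image, dtype=np.float64), config.patch_size, config.mirror_px
    )
    state = InternalState(input=padded)
    pass_input = padded
    for pass_idx in range(1, config.max_passes + 1):
        if hasattr(predictor, "begin_pass"):
            predictor.begin_pass(pass_idx)
        n_before = len(state.objects)
        kaizen_pass(pass_input, predictor, config, state=state, source_pass=pass_idx)
        n_new = len(state.objects) - n_before
        logger.info("pass %d: %d new objects, loss %.6g", pass_idx, n_new, state.loss)
        if n_new == 0:
            break
        residual = np.clip(crop_padding(state.error, config.patch_size), 0.0, None)
        pass_input = pad_for_inference(residual, config.patch_size, config.mirror_px)
    return state
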