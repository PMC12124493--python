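"""Instance-segmentation scoring: IoU matching and average precision.

A predicted instance is a true positive at threshold tau when it can be
matched one-to-one with a ground-truth instance at IoU strictly above tau
(greedy matching in descending IoU order, the convention of the standard
nuclei-segmentation benchmarks). Per-image average precision is

    AP_tau = TP / (TP + FN + FP),

and a test-set score is the arithmetic mean of per-image APs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "MatchResult",
    "iou",
    "match_instances",
    "average_precision",
    "evaluate_set",
    "DEFAULT_TAUS",
]

DEFAULT_TAUS = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class MatchResult:
    tau: float
    tp: int
    fp: int
    fn: int
    pairs: List[Tuple[int, int, float]] = field(default_factory=list)
    # (pred label, truth label, IoU) for each matched pair


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks (0 when both empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def _pairwise_iou(pred: np.ndarray, truth: np.ndarray):
    """IoU matrix between all pred and truth instances via a joint
    contingency table (single pass over the pixels)."""
    pred_ids = np.unique(pred)
    pred_ids = pred_ids[pred_ids > 0]
    truth_ids = np.unique(truth)
    truth_ids = truth_ids[truth_ids > 0]
    if pred_ids.size == 0 or truth_ids.size == 0:
        return pred_ids, truth_ids, np.zeros((pred_ids.size, truth_ids.size))
    pi = np.searchsorted(pred_ids, pred.ravel())
    ti = np.searchsorted(truth_ids, truth.ravel())
    both = (pred.ravel() > 0) & (truth.ravel() > 0)
    inter = np.zeros((pred_ids.size, truth_ids.size))
    np.add.at(inter, (pi[both], ti[both]), 1.0)
    areas_p = np.bincount(pi[pred.ravel() > 0], minlength=pred_ids.size)
    areas_t = np.bincount(ti[truth.ravel() > 0], minlength=truth_ids.size)
    union = areas_p[:, None] + areas_t[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.where(union > 0, inter / union, 0.0)
    return pred_ids, truth_ids, mat


def match_instances(pred: np.ndarray, truth: np.ndarray, tau: float) -> MatchResult:
    """Greedy one-to-one matching of instances with IoU strictly above tau.

    Candidate pairs are taken in descending IoU order (ties by smallest
    (pred, truth) label pair); each instance participates in at most one
    match. Unmatched predictions count as FP, unmatched truths as FN.
    """
    if pred.shape != truth.shape:
        raise ValueError("pred and truth label maps must share a shape")
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must be in (0, 1]")
    pred_ids, truth_ids, mat = _pairwise_iou(pred, truth)
    cand = [
        (mat[i, j], int(pred_ids[i]), int(truth_ids[j]))
        for i in range(pred_ids.size)
        for j in range(truth_ids.size)
        if mat[i, j] > tau
    ]
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p, used_t = set(), set()
    pairs = []
    for v, p, t in cand:
        if p in used_p or t in used_t:
            continue
        used_p.add(p)
        used_t.add(t)
        pairs.append((p, t, float(v)))
    tp = len(pairs)
    return MatchResult(
        tau=tau, tp=tp,
        fp=int(pred_ids.size - tp),
        fn=int(truth_ids.size - tp),
        pairs=pairs,
    )


def average_precision(result: MatchResult) -> float:
    """AP = TP / (TP + FN + FP); 1.0 for the empty-vs-empty image."""
    denom = result.tp + result.fn + result.fp
    if denom == 0:
        return 1.0
    return result.tp / denom


def evaluate_set(
    preds: Sequence[np.ndarray],
    truths: Sequence[np.ndarray],
    taus: Sequence[float] = DEFAULT_TAUS,
) -> pd.DataFrame:
    """Mean AP across images at each threshold.

    Returns a one-row-per-image DataFrame plus a ``"mean"`` row, columns
    indexed by tau.
    """
    if len(preds) != len(truths):
        raise ValueError("preds and truths must have equal length")
    rows = {}
    for i, (p, t) in enumerate(zip(preds, truths)):
        rows[i] = {
            tau: average_precision(match_instances(p, t, tau)) for tau in taus
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.loc["mean"] = table.mean(axis=0)
    table.columns.name = "tau"
    return table
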