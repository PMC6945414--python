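"""Empirical ROC curves, whole-curve AUC and the concordance (c) statistic.

An empirical ROC curve is the staircase polyline traced in (FPR, TPR) space
as a decision threshold sweeps from above the highest classification score
down to below the lowest.  Each actual positive passed moves the curve up by
1/P, each actual negative moves it right by 1/N, and a group of tied scores
mixing ``a`` positives with ``b`` negatives produces a single diagonal
segment of rise a/P and run b/N.  With that tie convention, the trapezoidal
area under the polyline equals the c statistic

    c = (1/PN) * sum_j sum_k H(g(p_j) - g(n_k)),

where H scores a correctly ranked positive/negative pair as 1, a tie as 0.5
and an inversion as 0 — the classical AUC = c equivalence for binary
(uncensored) outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

__all__ = [
    "COORD_TOL",
    "DegenerateClassError",
    "ScoredDataset",
    "EmpiricalROC",
    "score_groups",
    "build_empirical_roc",
    "interpolate_on_curve",
    "auc_trapezoid",
    "c_statistic",
]

#: Absolute tolerance used when matching query coordinates to curve vertices.
COORD_TOL = 1e-9


class DegenerateClassError(ValueError):
    """Raised when an operation needs both classes but one is absent."""


@dataclass(frozen=True)
class ScoredDataset:
    """Per-instance classification scores with binary ground-truth labels.

    Higher score means "more positive"; label 1 marks an actual positive.
    Scores must be finite and labels strictly binary.  Use
    ``orientation="lower_is_positive"`` at ingest (see :mod:`rocpartials.io`)
    to negate scores of a test where low values indicate disease.
    """

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels)
        if scores.ndim != 1 or labels.ndim != 1:
            raise ValueError("scores and labels must be one-dimensional")
        if scores.shape != labels.shape:
            raise ValueError(
                f"scores ({scores.size}) and labels ({labels.size}) differ in length"
            )
        if scores.size == 0:
            raise ValueError("dataset is empty")
        if not np.all(np.isfinite(scores)):
            raise ValueError("all scores must be finite")
        if not np.all(np.isin(labels, (0, 1))):
            raise ValueError("labels must be strictly binary (0 or 1)")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels.astype(np.int64))

    @property
    def P(self) -> int:
        """Number of actual positives."""
        return int(self.labels.sum())

    @property
    def N(self) -> int:
        """Number of actual negatives."""
        return int(self.labels.size - self.labels.sum())

    @property
    def positive_scores(self) -> np.ndarray:
        """Scores of actual positives, sorted descending."""
        return np.sort(self.scores[self.labels == 1])[::-1]

    @property
    def negative_scores(self) -> np.ndarray:
        """Scores of actual negatives, sorted descending."""
        return np.sort(self.scores[self.labels == 0])[::-1]

    def require_both_classes(self) -> None:
        if self.P == 0:
            raise DegenerateClassError("no actual positives (all labels are 0)")
        if self.N == 0:
            raise DegenerateClassError("no actual negatives (all labels are 1)")


@dataclass(frozen=True)
class EmpiricalROC:
    """Ordered polyline of (FPR, TPR) vertices with associated thresholds.

    ``vertices`` is an (m, 2) array running from (0, 0) to (1, 1) with both
    coordinates non-decreasing.  ``thresholds[i]`` is the score at or above
    which instances are called positive to reach vertex ``i`` (+inf for the
    origin).  Collinear consecutive segments are merged, so a run of
    positives at distinct scores is one vertical segment.
    """

    vertices: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        t = np.asarray(self.thresholds, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("vertices must be an (m, 2) array with m >= 2")
        if t.shape != (v.shape[0],):
            raise ValueError("thresholds must align with vertices")
        if not (np.allclose(v[0], [0.0, 0.0]) and np.allclose(v[-1], [1.0, 1.0])):
            raise ValueError("curve must run from (0, 0) to (1, 1)")
        if np.any(np.diff(v, axis=0) < -COORD_TOL):
            raise ValueError("FPR and TPR must be non-decreasing along the curve")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "thresholds", t)

    @property
    def fpr(self) -> np.ndarray:
        return self.vertices[:, 0]

    @property
    def tpr(self) -> np.ndarray:
        return self.vertices[:, 1]


def score_groups(data: ScoredDataset) -> Iterator[tuple[float, int, int]]:
    """Yield (score, n_positives, n_negatives) per tied group, descending."""
    uniq, inv = np.unique(data.scores, return_inverse=True)
    pos = np.bincount(inv, weights=data.labels, minlength=uniq.size)
    tot = np.bincount(inv, minlength=uniq.size)
    for i in range(uniq.size - 1, -1, -1):
        a = int(round(pos[i]))
        yield float(uniq[i]), a, int(tot[i]) - a


def _collapse_collinear(
    counts: list[tuple[int, int]], thresholds: list[float]
) -> tuple[list[tuple[int, int]], list[float]]:
    """Drop interior vertices lying on a straight run of the staircase.

    ``counts`` holds integer (negatives-consumed, positives-consumed) pairs so
    collinearity is decided by an exact integer cross product.
    """
    kept = [0]
    for i in range(1, len(counts) - 1):
        x0, y0 = counts[kept[-1]]
        x1, y1 = counts[i]
        x2, y2 = counts[i + 1]
        if (x1 - x0) * (y2 - y1) == (x2 - x1) * (y1 - y0):
            continue
        kept.append(i)
    kept.append(len(counts) - 1)
    return [counts[i] for i in kept], [thresholds[i] for i in kept]


def build_empirical_roc(data: ScoredDataset) -> EmpiricalROC:
    """Trace the empirical ROC staircase of a scored dataset.

    Thresholds sweep descending; tied score groups become single diagonal
    segments so that the trapezoidal area equals the c statistic.
    """
    data.require_both_classes()
    P, N = data.P, data.N
    counts: list[tuple[int, int]] = [(0, 0)]
    thresholds: list[float] = [math.inf]
    fp = tp = 0
    for score, a, b in score_groups(data):
        tp += a
        fp += b
        counts.append((fp, tp))
        thresholds.append(score)
    counts, thresholds = _collapse_collinear(counts, thresholds)
    vertices = np.array(counts, dtype=float) / [N, P]
    return EmpiricalROC(vertices=vertices, thresholds=np.asarray(thresholds))


def interpolate_on_curve(roc: EmpiricalROC, value: float, axis: str = "fpr") -> float:
    """Evaluate the curve r(x) or its inverse r^{-1}(y) by linear interpolation.

    ``axis="fpr"`` returns r(value): the maximal TPR attained at that FPR
    (the top of a vertical segment).  ``axis="tpr"`` returns r^{-1}(value):
    the minimal FPR attaining that TPR (the left end of a horizontal
    segment).  These conventions make the vertical and horizontal partial
    area integrals additive over a partition of the staircase.
    """
    if not -COORD_TOL <= value <= 1.0 + COORD_TOL:
        raise ValueError(f"coordinate {value!r} outside [0, 1]")
    value = min(max(value, 0.0), 1.0)
    xs, ys = roc.fpr, roc.tpr
    if axis == "fpr":
        hit = np.abs(xs - value) <= COORD_TOL
        if hit.any():
            return float(ys[hit].max())
        i = int(np.searchsorted(xs, value))  # xs[i-1] < value < xs[i]
        frac = (value - xs[i - 1]) / (xs[i] - xs[i - 1])
        return float(ys[i - 1] + frac * (ys[i] - ys[i - 1]))
    if axis == "tpr":
        hit = np.abs(ys - value) <= COORD_TOL
        if hit.any():
            return float(xs[hit].min())
        i = int(np.searchsorted(ys, value))
        frac = (value - ys[i - 1]) / (ys[i] - ys[i - 1])
        return float(xs[i - 1] + frac * (xs[i] - xs[i - 1]))
    raise ValueError(f"axis must be 'fpr' or 'tpr', got {axis!r}")


def auc_trapezoid(roc: EmpiricalROC) -> float:
    """Trapezoidal area under the empirical ROC polyline."""
    return float(np.trapezoid(roc.tpr, roc.fpr))


def c_statistic(data: ScoredDataset) -> float:
    """Concordance: proportion of positive/negative pairs ranked correctly.

    Ties in score count one half.  Equals :func:`auc_trapezoid` of the same
    data's empirical curve.
    """
    data.require_both_classes()
    diff = data.positive_scores[:, None] - data.negative_scores[None, :]
    return float(np.mean((diff > 0) + 0.5 * (diff == 0)))
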