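"""Resolving user-specified boundaries into on-curve partial ranges.

A range along a single axis does not uniquely pin down a partial curve: at a
vertical segment several TPR values share one FPR, so a boundary given as an
FPR value is ambiguous.  The resolution rules used here are:

* leftmost part — left endpoint: the most southwest point at x1; right
  endpoint: the most northeast point at x2;
* every other part — both endpoints: the most northeast matching point.

Adjacent parts then share their boundary vertex exactly, the parts jointly
cover the curve without overlap, and the shared vertices contribute zero
area twice, which is what makes the partial sums exact.  A boundary falling
inside a tied-group diagonal resolves to the proportional point on the
diagonal.

:func:`range_to_weights` converts a resolved range into the per-instance
weight vectors of the partial c statistic: each instance's weight is the
fraction of its ROC step inside the range, instances of one tied group
sharing a single group-uniform fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .concordance import WeightVectors
from .partial_areas import PartialRange, point_on_curve
from .roc import COORD_TOL, EmpiricalROC, ScoredDataset, score_groups

__all__ = [
    "PartitionSpec",
    "resolve_partition",
    "range_to_weights",
    "point_at_fpr",
    "point_at_tpr",
]


@dataclass(frozen=True)
class PartitionSpec:
    """Boundaries (FPR or TPR values) or an explicit list of partial ranges.

    Boundary lists must be strictly ascending from 0 to 1, yielding a
    spanning partition.  Explicit ranges may cover any non-overlapping
    subset of the curve, including degenerate (zero-extent) pieces.
    """

    fpr_boundaries: tuple[float, ...] | None = None
    tpr_boundaries: tuple[float, ...] | None = None
    ranges: tuple[PartialRange, ...] | None = None

    def __post_init__(self) -> None:
        given = [
            f
            for f in (self.fpr_boundaries, self.tpr_boundaries, self.ranges)
            if f is not None
        ]
        if len(given) != 1:
            raise ValueError(
                "specify exactly one of fpr_boundaries, tpr_boundaries or ranges"
            )
        for name in ("fpr_boundaries", "tpr_boundaries"):
            bounds = getattr(self, name)
            if bounds is None:
                continue
            bounds = tuple(float(b) for b in bounds)
            if len(bounds) < 2:
                raise ValueError(f"{name} needs at least two values")
            if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
                raise ValueError(f"{name} must be strictly ascending: {bounds}")
            if any(not 0.0 <= b <= 1.0 for b in bounds):
                raise ValueError(f"{name} values must lie in [0, 1]: {bounds}")
            if bounds[0] != 0.0 or bounds[-1] != 1.0:
                raise ValueError(f"{name} must start at 0 and end at 1 for a spanning partition")
            object.__setattr__(self, name, bounds)
        if self.ranges is not None:
            object.__setattr__(self, "ranges", tuple(self.ranges))


def point_at_fpr(roc: EmpiricalROC, x: float, prefer: str = "northeast") -> tuple[float, float]:
    """The on-curve point at FPR=x, disambiguated toward a corner.

    ``prefer="northeast"`` picks the highest TPR at that FPR, ``"southwest"``
    the lowest.  Off-vertex queries interpolate (unique point).
    """
    xs, ys = roc.fpr, roc.tpr
    hit = np.abs(xs - x) <= COORD_TOL
    if hit.any():
        y = float(ys[hit].max() if prefer == "northeast" else ys[hit].min())
        return x, y
    i = int(np.searchsorted(xs, x))
    frac = (x - xs[i - 1]) / (xs[i] - xs[i - 1])
    return x, float(ys[i - 1] + frac * (ys[i] - ys[i - 1]))


def point_at_tpr(roc: EmpiricalROC, y: float, prefer: str = "northeast") -> tuple[float, float]:
    """The on-curve point at TPR=y; northeast picks the largest FPR."""
    xs, ys = roc.fpr, roc.tpr
    hit = np.abs(ys - y) <= COORD_TOL
    if hit.any():
        x = float(xs[hit].max() if prefer == "northeast" else xs[hit].min())
        return x, y
    i = int(np.searchsorted(ys, y))
    frac = (y - ys[i - 1]) / (ys[i] - ys[i - 1])
    return float(xs[i - 1] + frac * (xs[i] - xs[i - 1])), y


def _ranges_from_boundaries(
    roc: EmpiricalROC, boundaries: Sequence[float], axis: str
) -> list[PartialRange]:
    locate = point_at_fpr if axis == "fpr" else point_at_tpr
    points = [locate(roc, boundaries[0], prefer="southwest")]
    points += [locate(roc, b, prefer="northeast") for b in boundaries[1:]]
    ranges = []
    for (xa, ya), (xb, yb) in zip(points, points[1:]):
        ranges.append(PartialRange(x1=xa, x2=xb, y1=ya, y2=yb))
    return ranges


def resolve_partition(roc: EmpiricalROC, spec: PartitionSpec) -> list[PartialRange]:
    """Resolve a partition spec to ordered, non-overlapping on-curve ranges."""
    if spec.fpr_boundaries is not None:
        return _ranges_from_boundaries(roc, spec.fpr_boundaries, "fpr")
    if spec.tpr_boundaries is not None:
        return _ranges_from_boundaries(roc, spec.tpr_boundaries, "tpr")
    assert spec.ranges is not None
    for prange in spec.ranges:
        for label, (x, y) in (
            ("left endpoint", (prange.x1, prange.y1)),
            ("right endpoint", (prange.x2, prange.y2)),
        ):
            if not point_on_curve(roc, x, y):
                raise ValueError(f"{label} ({x}, {y}) does not lie on the ROC curve")
    for r1, r2 in zip(spec.ranges, spec.ranges[1:]):
        if r2.x1 < r1.x2 - COORD_TOL or r2.y1 < r1.y2 - COORD_TOL:
            raise ValueError(
                "overlapping partial curves are not supported: "
                f"[{r1.x1},{r1.x2}]x[{r1.y1},{r1.y2}] then [{r2.x1},{r2.x2}]x[{r2.y1},{r2.y2}]"
            )
    return list(spec.ranges)


def _overlap(lo: float, hi: float, a: float, b: float) -> float:
    return max(0.0, min(hi, b) - max(lo, a))


def range_to_weights(
    data: ScoredDataset, roc: EmpiricalROC, prange: PartialRange
) -> WeightVectors:
    """Per-instance stripe weights of a resolved partial range.

    A positive's weight is the fraction of its tied group's vertical extent
    inside [y1, y2]; a negative's, the fraction of its group's horizontal
    extent inside [x1, x2].  Weights across a spanning partition sum to 1
    per instance exactly, and the resulting partial c statistic equals the
    concordant partial AUC of the range.
    """
    for label, (x, y) in (
        ("left endpoint", (prange.x1, prange.y1)),
        ("right endpoint", (prange.x2, prange.y2)),
    ):
        if not point_on_curve(roc, x, y):
            raise ValueError(f"{label} ({x}, {y}) does not lie on the ROC curve")
    P, N = data.P, data.N
    w_plus = np.zeros(P)
    w_minus = np.zeros(N)
    tp = fp = 0
    for _score, a, b in score_groups(data):
        if a > 0:
            gy0, gy1 = tp / P, (tp + a) / P
            frac = _overlap(gy0, gy1, prange.y1, prange.y2) / (gy1 - gy0)
            w_plus[tp : tp + a] = frac
        if b > 0:
            gx0, gx1 = fp / N, (fp + b) / N
            frac = _overlap(gx0, gx1, prange.x1, prange.x2) / (gx1 - gx0)
            w_minus[fp : fp + b] = frac
        tp += a
        fp += b
    return WeightVectors(w_plus=w_plus, w_minus=w_minus)
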