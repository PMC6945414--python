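"""Vertical, horizontal and concordant partial areas under an ROC curve.

For a partial curve bounded by FPR in [x1, x2] and TPR in [y1, y2]:

    pAUC    = integral of r(x) dx over [x1, x2]        (average sensitivity)
    pAUC_x  = integral of 1 - r^{-1}(y) dy over [y1, y2] (average specificity)
    pAUC_c  = (pAUC + pAUC_x) / 2                       (concordant partial AUC)

pAUC_c equals the partial c statistic of the same partial curve and sums to
AUC = c over any spanning, non-overlapping partition; the equal weighting of
the two integrals is forced by that equivalence, and the halving accounts
for the region counted by both perspectives.  All integrals are computed
segment-exactly on the polyline, so the identities hold to machine
precision.  McClish's standardized partial area (sPA), which removes the
area below the chance diagonal and rescales to [0.5, 1], is included for
comparison, as are the range-normalized variants of all three areas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .roc import (
    COORD_TOL,
    EmpiricalROC,
    ScoredDataset,
    auc_trapezoid,
    build_empirical_roc,
    c_statistic,
)

__all__ = [
    "PartialRange",
    "MeasureReport",
    "point_on_curve",
    "pauc_vertical",
    "pauc_horizontal",
    "pauc_concordant",
    "concordant_from_components",
    "NormalizedMeasures",
    "normalized_measures",
    "spa_from_pauc",
    "spa_mcclish",
    "compute_report",
]


@dataclass(frozen=True)
class PartialRange:
    """A contiguous piece of the curve: FPR in [x1, x2], TPR in [y1, y2].

    Both endpoints (x1, y1) and (x2, y2) must lie on the curve polyline.
    Degenerate pieces (zero width or zero height) are permitted — a purely
    vertical partial curve has pAUC 0 but positive pAUC_x.
    """

    x1: float
    x2: float
    y1: float
    y2: float

    def __post_init__(self) -> None:
        for name, v in (("x1", self.x1), ("x2", self.x2), ("y1", self.y1), ("y2", self.y2)):
            if not -COORD_TOL <= v <= 1.0 + COORD_TOL:
                raise ValueError(f"{name}={v!r} outside [0, 1]")
            object.__setattr__(self, name, min(max(float(v), 0.0), 1.0))
        if self.x1 > self.x2 + COORD_TOL:
            raise ValueError(f"reversed FPR bounds: [{self.x1}, {self.x2}]")
        if self.y1 > self.y2 + COORD_TOL:
            raise ValueError(f"reversed TPR bounds: [{self.y1}, {self.y2}]")

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1


def point_on_curve(roc: EmpiricalROC, x: float, y: float) -> bool:
    """Whether (x, y) lies on the curve polyline (within COORD_TOL)."""
    v = roc.vertices
    x0, y0 = v[:-1, 0], v[:-1, 1]
    x1, y1 = v[1:, 0], v[1:, 1]
    inbox = (
        (np.minimum(x0, x1) - COORD_TOL <= x)
        & (x <= np.maximum(x0, x1) + COORD_TOL)
        & (np.minimum(y0, y1) - COORD_TOL <= y)
        & (y <= np.maximum(y0, y1) + COORD_TOL)
    )
    cross = np.abs((x - x0) * (y1 - y0) - (y - y0) * (x1 - x0))
    return bool(np.any(inbox & (cross <= COORD_TOL)))


def _require_on_curve(roc: EmpiricalROC, prange: PartialRange) -> None:
    for label, (x, y) in (
        ("left endpoint (x1, y1)", (prange.x1, prange.y1)),
        ("right endpoint (x2, y2)", (prange.x2, prange.y2)),
    ):
        if not point_on_curve(roc, x, y):
            raise ValueError(f"{label} = ({x}, {y}) does not lie on the ROC curve")


def pauc_vertical(roc: EmpiricalROC, x1: float, x2: float) -> float:
    """Vertical partial AUC: exact trapezoidal integral of r(x) over [x1, x2]."""
    if x1 > x2:
        raise ValueError(f"reversed FPR bounds: [{x1}, {x2}]")
    if not (-COORD_TOL <= x1 and x2 <= 1.0 + COORD_TOL):
        raise ValueError(f"FPR bounds [{x1}, {x2}] outside [0, 1]")
    v = roc.vertices
    xa, xb = v[:-1, 0], v[1:, 0]
    ya, yb = v[:-1, 1], v[1:, 1]
    lo = np.maximum(xa, x1)
    hi = np.minimum(xb, x2)
    dx = xb - xa
    live = (hi - lo > 0) & (dx > 0)
    if not live.any():
        return 0.0
    frac_lo = (lo[live] - xa[live]) / dx[live]
    frac_hi = (hi[live] - xa[live]) / dx[live]
    y_lo = ya[live] + frac_lo * (yb[live] - ya[live])
    y_hi = ya[live] + frac_hi * (yb[live] - ya[live])
    return float(np.sum((hi[live] - lo[live]) * 0.5 * (y_lo + y_hi)))


def pauc_horizontal(roc: EmpiricalROC, y1: float, y2: float) -> float:
    """Horizontal partial AUC: exact integral of 1 - r^{-1}(y) over [y1, y2].

    This is the area between the curve and the right border x = 1, the
    specificity analog of the vertical partial area; over the whole range it
    equals the AUC.
    """
    if y1 > y2:
        raise ValueError(f"reversed TPR bounds: [{y1}, {y2}]")
    if not (-COORD_TOL <= y1 and y2 <= 1.0 + COORD_TOL):
        raise ValueError(f"TPR bounds [{y1}, {y2}] outside [0, 1]")
    v = roc.vertices
    xa, xb = v[:-1, 0], v[1:, 0]
    ya, yb = v[:-1, 1], v[1:, 1]
    lo = np.maximum(ya, y1)
    hi = np.minimum(yb, y2)
    dy = yb - ya
    live = (hi - lo > 0) & (dy > 0)
    if not live.any():
        return 0.0
    frac_lo = (lo[live] - ya[live]) / dy[live]
    frac_hi = (hi[live] - ya[live]) / dy[live]
    x_lo = xa[live] + frac_lo * (xb[live] - xa[live])
    x_hi = xa[live] + frac_hi * (xb[live] - xa[live])
    return float(np.sum((hi[live] - lo[live]) * 0.5 * ((1 - x_lo) + (1 - x_hi))))


def concordant_from_components(pauc: float, pauc_x: float) -> float:
    """Concordant partial AUC from its two components: (pAUC + pAUC_x) / 2."""
    return 0.5 * pauc + 0.5 * pauc_x


def pauc_concordant(roc: EmpiricalROC, prange: PartialRange) -> float:
    """Concordant partial AUC of an on-curve partial range."""
    _require_on_curve(roc, prange)
    return concordant_from_components(
        pauc_vertical(roc, prange.x1, prange.x2),
        pauc_horizontal(roc, prange.y1, prange.y2),
    )


class NormalizedMeasures(NamedTuple):
    pauc_norm: float
    pauc_x_norm: float
    pauc_c_norm: float


def normalized_measures(roc: EmpiricalROC, prange: PartialRange) -> NormalizedMeasures:
    """Range-normalized areas, each in [0, 1].

    pAUC~ = pAUC/(x2-x1); pAUC_x~ = pAUC_x/(y2-y1);
    pAUC_c~ = (pAUC + pAUC_x)/((x2-x1) + (y2-y1)).
    Raises when the corresponding denominator has zero extent.
    """
    _require_on_curve(roc, prange)
    dx, dy = prange.width, prange.height
    if dx <= 0 and dy <= 0:
        raise ValueError("range has zero extent on both axes")
    pauc = pauc_vertical(roc, prange.x1, prange.x2)
    pauc_x = pauc_horizontal(roc, prange.y1, prange.y2)
    if dx <= 0:
        raise ValueError("zero-width FPR range: normalized pAUC undefined")
    if dy <= 0:
        raise ValueError("zero-height TPR range: normalized pAUC_x undefined")
    return NormalizedMeasures(pauc / dx, pauc_x / dy, (pauc + pauc_x) / (dx + dy))


def spa_from_pauc(pauc: float, x1: float, x2: float) -> float:
    """McClish's standardized partial area from a known pAUC value.

    sPA = (1/2) * [1 + (pAUC - A_dg) / (A_max - A_dg)] with
    A_dg = (x2 - x1)(x1 + x2)/2 the area under the chance diagonal over the
    range and A_max = x2 - x1 the full rectangle.  A perfectly informative
    range scores 1, a chance-level one 0.5; a curve dipping under the
    diagonal yields a value below 0.5, possibly negative.
    """
    if x2 <= x1:
        raise ValueError(f"zero-width FPR range [{x1}, {x2}]")
    width = x2 - x1
    a_dg = width * (x1 + x2) / 2.0
    a_max = width
    return 0.5 * (1.0 + (pauc - a_dg) / (a_max - a_dg))


def spa_mcclish(roc: EmpiricalROC, x1: float, x2: float) -> float:
    """McClish's standardized partial area of the curve over FPR [x1, x2]."""
    return spa_from_pauc(pauc_vertical(roc, x1, x2), x1, x2)


@dataclass(frozen=True)
class MeasureReport:
    """Per-part table of all measures plus whole-curve summary.

    ``parts`` has one row per partial curve with the raw, concordant,
    normalized and standardized measures; ``whole`` carries the whole-curve
    AUC, c and both average-precision orientations.  For a spanning
    partition the column sums of pAUC, pAUC_x, pAUC_c and c_delta all equal
    AUC = c.
    """

    parts: pd.DataFrame
    whole: dict[str, float] = field(default_factory=dict)

    SUM_COLUMNS = ("pauc", "pauc_c", "pauc_x", "c_delta")

    def sums(self) -> dict[str, float]:
        return {col: float(self.parts[col].sum()) for col in self.SUM_COLUMNS}


def compute_report(
    data: ScoredDataset,
    partition: "Sequence[float] | object",
) -> MeasureReport:
    """Evaluate every measure per part of a partition plus the whole curve.

    ``partition`` is a PartitionSpec, a list of FPR boundaries, or a list of
    PartialRange objects.  Normalized measures undefined on a degenerate
    part are reported as NaN rather than raised.
    """
    from .concordance import WeightVectors, local_c, normalize_partial_c, partial_c
    from .ranges import PartitionSpec, range_to_weights, resolve_partition
    from .simulate import auprc_pair

    roc = build_empirical_roc(data)
    if isinstance(partition, PartitionSpec):
        spec = partition
    elif len(partition) and isinstance(partition[0], PartialRange):
        spec = PartitionSpec(ranges=tuple(partition))
    else:
        spec = PartitionSpec(fpr_boundaries=tuple(partition))
    ranges = resolve_partition(roc, spec)

    P, N = data.P, data.N
    rows = []
    for i, prange in enumerate(ranges, start=1):
        pauc = pauc_vertical(roc, prange.x1, prange.x2)
        pauc_x = pauc_horizontal(roc, prange.y1, prange.y2)
        pauc_c = concordant_from_components(pauc, pauc_x)
        weights = range_to_weights(data, roc, prange)
        c_delta = partial_c(data, weights)
        dx, dy = prange.width, prange.height
        pos_idx = np.nonzero(weights.w_plus > 1e-12)[0]
        neg_idx = np.nonzero(weights.w_minus > 1e-12)[0]
        rows.append(
            {
                "part": i,
                "fpr_lo": prange.x1,
                "fpr_hi": prange.x2,
                "tpr_lo": prange.y1,
                "tpr_hi": prange.y2,
                "pauc": pauc,
                "pauc_c": pauc_c,
                "pauc_x": pauc_x,
                "c_delta": c_delta,
                "pauc_norm": pauc / dx if dx > 0 else math.nan,
                "pauc_x_norm": pauc_x / dy if dy > 0 else math.nan,
                "pauc_c_norm": (pauc + pauc_x) / (dx + dy) if dx + dy > 0 else math.nan,
                "c_delta_norm": normalize_partial_c(c_delta, weights, P, N),
                "spa": spa_from_pauc(pauc, prange.x1, prange.x2) if dx > 0 else math.nan,
                "local_c": (
                    local_c(data, pos_idx, neg_idx)
                    if pos_idx.size and neg_idx.size
                    else math.nan
                ),
            }
        )
    ap_plus, ap_minus = auprc_pair(data)
    whole = {
        "auc": auc_trapezoid(roc),
        "c": c_statistic(data),
        "ap_plus": ap_plus,
        "ap_minus": ap_minus,
    }
    return MeasureReport(parts=pd.DataFrame(rows), whole=whole)
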