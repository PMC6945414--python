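"""The concordance matrix and partial c statistics.

The concordance matrix lays out every positive/negative pair of a dataset on
a P x N grid, rows holding positives and columns negatives, both ordered by
descending score away from the origin.  Cell (j, k) records
H(g(p_j) - g(n_k)): 1 for a correctly ranked pair, 0.5 for a tie, 0 for an
inversion.  The mean of the grid is the c statistic, and the staircase
border separating the concordant from the discordant cells — run diagonally
through rectangular blocks of ties — is, rescaled to the unit square,
exactly the empirical ROC curve.

The partial c statistic c_delta restricts concordance to the row and column
stripes of a partial curve.  With per-instance weights w+ (positives) and
w- (negatives) in [0, 1],

    c_delta = (1/2PN) * [ sum_jk w+_j H_jk  +  sum_jk w-_k H_jk ],

the pooled normalization under which partial c statistics of a spanning,
non-overlapping partition sum exactly to c and each part equals its
concordant partial AUC.  A per-stripe normalization (dividing the two sums
by 2N*sum(w+) and 2P*sum(w-)) is also available for comparison but does not
sum to c.  The local c statistic — concordance inside one block of the grid
only — is provided to document why the stripe form is needed: no convex
combination of local values recovers c in general.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .roc import ScoredDataset, _collapse_collinear, c_statistic

__all__ = [
    "ConcordanceMatrix",
    "WeightVectors",
    "build_concordance_matrix",
    "matrix_border_path",
    "local_c",
    "partial_c",
    "normalize_partial_c",
]


def _heaviside(pos_desc: np.ndarray, neg_desc: np.ndarray) -> np.ndarray:
    diff = pos_desc[:, None] - neg_desc[None, :]
    return (diff > 0) + 0.5 * (diff == 0)


@dataclass(frozen=True)
class ConcordanceMatrix:
    """P x N grid of pairwise ranking outcomes in {0, 0.5, 1}.

    Row j holds the j-th highest-scoring positive, column k the k-th
    highest-scoring negative, so scores increase toward the origin and the
    concordant cells pool in the corner pairing top positives with bottom
    negatives.
    """

    cells: np.ndarray
    pos_scores: np.ndarray
    neg_scores: np.ndarray

    @property
    def P(self) -> int:
        return self.cells.shape[0]

    @property
    def N(self) -> int:
        return self.cells.shape[1]

    @property
    def c(self) -> float:
        """Mean of all cells — the c statistic of the underlying data."""
        return float(self.cells.mean())


def build_concordance_matrix(data: ScoredDataset) -> ConcordanceMatrix:
    data.require_both_classes()
    pos = data.positive_scores
    neg = data.negative_scores
    return ConcordanceMatrix(cells=_heaviside(pos, neg), pos_scores=pos, neg_scores=neg)


def matrix_border_path(matrix: ConcordanceMatrix) -> np.ndarray:
    """Walk the concordant/discordant border of the grid, scaled to [0,1]^2.

    Starting at the origin with no instances consumed, a concordant cell
    means the current positive outranks the current negative and the path
    moves up; a discordant cell moves it right; a rectangular block of tied
    cells is crossed by its diagonal.  The result is vertex-for-vertex the
    empirical ROC curve of the same data, computed from the cell grid alone.
    """
    cells = matrix.cells
    P, N = matrix.P, matrix.N
    counts: list[tuple[int, int]] = [(0, 0)]
    j = k = 0
    while j < P or k < N:
        if j < P and k < N and cells[j, k] == 0.5:
            a = 1
            while j + a < P and cells[j + a, k] == 0.5:
                a += 1
            b = 1
            while k + b < N and cells[j, k + b] == 0.5:
                b += 1
            j += a
            k += b
        elif j < P and (k == N or cells[j, k] == 1.0):
            j += 1
        else:
            k += 1
        counts.append((k, j))
    counts, _ = _collapse_collinear(counts, [0.0] * len(counts))
    return np.array(counts, dtype=float) / [N, P]


def local_c(
    data: ScoredDataset,
    pos_subset: Sequence[int],
    neg_subset: Sequence[int],
) -> float:
    """Concordance restricted to one block of the matrix.

    Subsets index the descending-sorted positives and negatives (matrix rows
    and columns).  The local c statistic ignores every pair that straddles
    the block, so it is not additive to c across a partition.
    """
    data.require_both_classes()
    pos_idx = np.asarray(pos_subset, dtype=int)
    neg_idx = np.asarray(neg_subset, dtype=int)
    if pos_idx.size == 0 or neg_idx.size == 0:
        raise ValueError("pos_subset and neg_subset must both be non-empty")
    pos = data.positive_scores[pos_idx]
    neg = data.negative_scores[neg_idx]
    return float(_heaviside(pos, neg).mean())


@dataclass(frozen=True)
class WeightVectors:
    """Per-instance stripe weights for the partial c statistic.

    ``w_plus`` aligns with the descending-sorted positives (matrix rows),
    ``w_minus`` with the descending-sorted negatives (columns).  A weight is
    the fraction of that instance's ROC step lying inside the partial curve;
    across a spanning partition the weights of each instance sum to 1.
    """

    w_plus: np.ndarray
    w_minus: np.ndarray

    def __post_init__(self) -> None:
        wp = np.asarray(self.w_plus, dtype=float)
        wm = np.asarray(self.w_minus, dtype=float)
        for name, w in (("w_plus", wp), ("w_minus", wm)):
            if w.ndim != 1:
                raise ValueError(f"{name} must be one-dimensional")
            if np.any(w < -1e-12) or np.any(w > 1 + 1e-12):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        object.__setattr__(self, "w_plus", np.clip(wp, 0.0, 1.0))
        object.__setattr__(self, "w_minus", np.clip(wm, 0.0, 1.0))

    @classmethod
    def ones(cls, P: int, N: int) -> "WeightVectors":
        """Whole-curve weights: every instance fully included."""
        return cls(np.ones(P), np.ones(N))


def partial_c(
    data: ScoredDataset,
    weights: WeightVectors,
    normalization: str = "pooled",
) -> float:
    """Partial c statistic c_delta over weighted row and column stripes.

    With ``normalization="pooled"`` (default) the two stripe sums share the
    single denominator 2PN; integer weights reproduce the simple
    subset-of-rows/columns case, all-ones weights reproduce c exactly, and
    parts of a spanning partition sum to c.  ``normalization="stripe"``
    divides each sum by its own stripe size (2N*sum(w+) and 2P*sum(w-));
    this variant is already scaled to [0, 1] but is not additive.
    """
    data.require_both_classes()
    P, N = data.P, data.N
    wp, wm = weights.w_plus, weights.w_minus
    if wp.size != P or wm.size != N:
        raise ValueError(f"weights must have lengths P={P} and N={N}")
    if wp.sum() + wm.sum() == 0:
        raise ValueError("at least one weight must be positive")
    H = _heaviside(data.positive_scores, data.negative_scores)
    row_term = float(wp @ H.sum(axis=1))
    col_term = float(H.sum(axis=0) @ wm)
    if normalization == "pooled":
        return (row_term + col_term) / (2.0 * P * N)
    if normalization == "stripe":
        if wp.sum() == 0 or wm.sum() == 0:
            raise ValueError("stripe normalization needs both stripes non-empty")
        return row_term / (2.0 * N * wp.sum()) + col_term / (2.0 * P * wm.sum())
    raise ValueError(f"unknown normalization {normalization!r}")


def normalize_partial_c(c_delta: float, weights: WeightVectors, P: int, N: int) -> float:
    """Rescale a pooled c_delta by its stripe size: 2PN*c_delta/(N*sum(w+)+P*sum(w-)).

    The result lies in [0, 1] and equals c when the weights are all ones,
    making partial curves of different extents comparable.
    """
    denom = N * float(weights.w_plus.sum()) + P * float(weights.w_minus.sum())
    if denom <= 0:
        raise ValueError("cannot normalize: all weights are zero")
    return 2.0 * P * N * c_delta / denom
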