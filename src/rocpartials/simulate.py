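"""Synthetic score data, staircase fixtures and precision-recall baselines.

The score generator draws from the binormal model: negatives from
Normal(0, sd_neg) and positives from Normal(mean_separation, sd_pos), the
standard parametric picture of a diagnostic score.  Its closed-form AUC,

    AUC = Phi(mean_separation / sqrt(sd_pos^2 + sd_neg^2)),

calibrates the empirical c statistic of large simulated samples.  An
optional quantization step rounds scores onto a grid to inject ties, which
exercise the diagonal-segment handling of every measure.  Class imbalance is
set directly through the P and N counts.

Average precision (AUPRC) is provided in both class orientations: AP+ walks
positives as usual; AP- swaps the class roles and negates the scores so the
same statistic focuses on the negatives.  Step (rectangle) interpolation is
used, matching the usual average-precision estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .roc import ScoredDataset, score_groups

__all__ = [
    "SimulationConfig",
    "simulate_scores",
    "staircase_fixture",
    "average_precision",
    "auprc_pair",
    "binormal_auc",
    "auc_standard_error",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Binormal score-generator settings; same seed, same dataset."""

    P: int
    N: int
    mean_separation: float = 1.0
    sd_pos: float = 1.0
    sd_neg: float = 1.0
    tie_quantization: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.P < 1 or self.N < 1:
            raise ValueError(f"P and N must each be >= 1 (got P={self.P}, N={self.N})")
        if self.sd_pos <= 0 or self.sd_neg <= 0:
            raise ValueError("standard deviations must be positive")
        if self.tie_quantization is not None and self.tie_quantization <= 0:
            raise ValueError("tie_quantization must be a positive step size")


def simulate_scores(config: SimulationConfig) -> ScoredDataset:
    """Draw a binormal scored dataset, optionally quantized to inject ties."""
    rng = np.random.default_rng(config.seed)
    pos = rng.normal(config.mean_separation, config.sd_pos, size=config.P)
    neg = rng.normal(0.0, config.sd_neg, size=config.N)
    scores = np.concatenate([pos, neg])
    if config.tie_quantization is not None:
        scores = np.round(scores / config.tie_quantization) * config.tie_quantization
    labels = np.concatenate([np.ones(config.P, dtype=int), np.zeros(config.N, dtype=int)])
    return ScoredDataset(scores=scores, labels=labels)


# Descending-score label patterns (1 = positive).  The balanced pattern is the
# classic 20-instance staircase used throughout the ROC literature; scores are
# fixture-defined distinct values realizing the shape.
_FIXTURES = {
    "balanced": [1, 1, 0, 1, 1, 1, 0, 0, 1, 0, 1, 0, 1, 0, 0, 0, 1, 0, 1, 0],
    "imbalanced_5_15": [1, 0, 0, 1, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0, 0, 0, 1, 0, 0, 0],
    "vertical_end": [1, 1, 1, 0, 1, 0, 0, 1, 0, 0],
}


def staircase_fixture(style: str) -> ScoredDataset:
    """Small deterministic staircase datasets with distinct scores.

    ``balanced`` is a 10/10 staircase; ``imbalanced_5_15`` has five positives
    to fifteen negatives; ``vertical_end`` opens with a purely vertical
    segment at FPR=0, giving a partial curve with zero vertical-area
    component when restricted to it.
    """
    if style not in _FIXTURES:
        raise ValueError(f"unknown fixture style {style!r}; choose from {sorted(_FIXTURES)}")
    labels = np.array(_FIXTURES[style], dtype=int)
    n = labels.size
    scores = (n - np.arange(n)) / n  # distinct, descending
    return ScoredDataset(scores=scores, labels=labels)


def average_precision(data: ScoredDataset) -> float:
    """Average precision with step interpolation over descending score groups."""
    data.require_both_classes()
    P = data.P
    tp = fp = 0
    ap = 0.0
    for _score, a, b in score_groups(data):
        tp += a
        fp += b
        if a > 0:
            ap += (a / P) * (tp / (tp + fp))
    return ap


def auprc_pair(data: ScoredDataset) -> tuple[float, float]:
    """(AP+, AP-): average precision for positives and, after swapping class
    roles and negating scores, for negatives."""
    swapped = ScoredDataset(scores=-data.scores, labels=1 - data.labels)
    return average_precision(data), average_precision(swapped)


def binormal_auc(mean_separation: float, sd_pos: float = 1.0, sd_neg: float = 1.0) -> float:
    """Closed-form AUC of the binormal model: Phi(d / sqrt(sd+^2 + sd-^2))."""
    z = mean_separation / math.hypot(sd_pos, sd_neg)
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def auc_standard_error(auc: float, P: int, N: int) -> float:
    """Hanley-McNeil standard error of an empirical AUC estimate."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc) + (P - 1) * (q1 - auc * auc) + (N - 1) * (q2 - auc * auc)
    ) / (P * N)
    return math.sqrt(max(var, 0.0))
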