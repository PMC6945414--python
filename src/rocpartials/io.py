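"""Score-table reading and measure-report writing.

Score tables are delimited text (comma, tab or semicolon; sniffed) with a
header and at least the columns ``label`` (0/1, 1 = actual positive) and
``score`` (decimal).  Reports are written either as full-precision TSV or as
a human-readable table with percentages to one decimal place.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import TextIO

import numpy as np
import pandas as pd

from .partial_areas import MeasureReport
from .roc import ScoredDataset

__all__ = ["read_scores", "write_scores", "write_report"]


class ScoreTableError(ValueError):
    """A score table failed to parse; the message cites the file line."""


def read_scores(path: str | Path, orientation: str = "higher_is_positive") -> ScoredDataset:
    """Read a delimited score table into a ScoredDataset.

    ``orientation="lower_is_positive"`` negates the scores at ingest for
    tests where low values indicate the positive class.  Parse failures
    report 1-based file line numbers (the header is line 1).
    """
    if orientation not in ("higher_is_positive", "lower_is_positive"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    try:
        table = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pandas raises several parser error types
        raise ScoreTableError(f"{path}: cannot parse score table: {exc}") from exc
    for col in ("label", "score"):
        if col not in table.columns:
            raise ScoreTableError(f"{path}: missing required column {col!r}")
    labels_raw = table["label"]
    scores_raw = pd.to_numeric(table["score"], errors="coerce")
    bad_score = np.nonzero(~np.isfinite(scores_raw.to_numpy(dtype=float)))[0]
    if bad_score.size:
        line = int(bad_score[0]) + 2
        raise ScoreTableError(
            f"{path}: line {line}: non-numeric score {table['score'].iloc[bad_score[0]]!r}"
        )
    labels_num = pd.to_numeric(labels_raw, errors="coerce")
    bad_label = np.nonzero(~np.isin(labels_num.to_numpy(dtype=float), (0.0, 1.0)))[0]
    if bad_label.size:
        line = int(bad_label[0]) + 2
        raise ScoreTableError(
            f"{path}: line {line}: label must be 0 or 1, got {labels_raw.iloc[bad_label[0]]!r}"
        )
    scores = scores_raw.to_numpy(dtype=float)
    if orientation == "lower_is_positive":
        scores = -scores
    return ScoredDataset(scores=scores, labels=labels_num.to_numpy(dtype=int))


def write_scores(data: ScoredDataset, path: str | Path) -> None:
    """Write a ScoredDataset as a two-column TSV score table."""
    frame = pd.DataFrame({"label": data.labels, "score": data.scores})
    frame.to_csv(path, sep="\t", index=False)


def _format_text(report: MeasureReport, precision: int = 1) -> str:
    pct_cols = [
        "pauc",
        "pauc_c",
        "pauc_x",
        "c_delta",
        "pauc_norm",
        "pauc_x_norm",
        "pauc_c_norm",
        "c_delta_norm",
        "spa",
        "local_c",
    ]

    def pct(v: float) -> str:
        return "-" if pd.isna(v) else f"{100 * v:.{precision}f}%"

    lines = []
    header = ["i", "FPR range", "TPR range"] + pct_cols
    widths = [3, 14, 14] + [max(len(c), 7) for c in pct_cols]
    lines.append("  ".join(h.ljust(w) for h, w in zip(header, widths)))
    for _, row in report.parts.iterrows():
        cells = [
            str(int(row["part"])),
            f"[{row['fpr_lo']:.2f}, {row['fpr_hi']:.2f}]",
            f"[{row['tpr_lo']:.2f}, {row['tpr_hi']:.2f}]",
        ] + [pct(row[c]) for c in pct_cols]
        lines.append("  ".join(c.ljust(w) for c, w in zip(cells, widths)))
    sums = report.sums()
    sum_cells = ["sum", "-", "-"] + [
        pct(sums[c]) if c in sums else "-" for c in pct_cols
    ]
    lines.append("  ".join(c.ljust(w) for c, w in zip(sum_cells, widths)))
    w = report.whole
    lines.append(
        f"whole: AUC = {pct(w['auc'])}  c = {pct(w['c'])}  "
        f"AP+ = {pct(w['ap_plus'])}  AP- = {pct(w['ap_minus'])}"
    )
    return "\n".join(lines) + "\n"


def write_report(
    report: MeasureReport,
    path: str | Path | TextIO,
    fmt: str = "tsv",
    precision: int = 1,
) -> None:
    """Write a MeasureReport as TSV (full precision) or structured text.

    The TSV holds the per-part table, a ``sum`` row over the additive
    columns, and a ``whole`` row carrying AUC, c, AP+ and AP-.
    """
    if fmt == "tsv":
        sums = report.sums()
        rows = report.parts.to_dict("records")
        rows.append({"part": "sum", **sums})
        rows.append({"part": "whole", **report.whole})
        text = pd.DataFrame(rows).to_csv(sep="\t", index=False)
    elif fmt in ("text", "structured_text"):
        text = _format_text(report, precision=precision)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text)
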