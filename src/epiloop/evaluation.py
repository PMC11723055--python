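"""Confusion-matrix metrics and the (M, N) grid-search calibration.

Calibration evaluates one feature at a time as a single-feature detector:
the feature's value in each epoch is compared against M*AVE + N*STD of its
previous four values, with no vote.  Every (M, N) pair in the grid — 5x5 =
25 combinations by default — is scored per epoch with precision, accuracy,
recall and the F2 score

    F2 = 5*TP / (5*TP + 4*FN + FP),

the F-beta measure at beta = 2, which weights recall (missing a seizure)
four times as heavily as precision (a spurious stimulation).  The best pair
is the one maximising F2, with accuracy, recall, then smallest (M, N)
breaking ties.  The composed detector then uses the per-feature optima with
the 3-of-4 vote.

The recall printed in the source hardware literature contains a typo
(TP/(TP+TN)); the standard TP/(TP+FN) is the default here, with
``recall_formula="as_printed"`` available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .features import FEATURE_NAMES, feature_series
from .signal_io import Recording, epoch_matrix
from .thresholding import FIFO_DEPTH


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Fractions in [0, 1]; a ratio with zero denominator is None."""

    precision: float | None
    accuracy: float | None
    recall: float | None
    f2: float | None


def confusion(labels: Sequence[bool], preds: Sequence[bool]) -> ConfusionCounts:
    """Standard 2x2 tally of per-epoch labels against predictions."""
    labels = np.asarray(labels, dtype=bool)
    preds = np.asarray(preds, dtype=bool)
    if labels.shape != preds.shape:
        raise ValueError(
            f"labels ({labels.shape}) and predictions ({preds.shape}) differ")
    return ConfusionCounts(
        tp=int(np.sum(labels & preds)),
        fp=int(np.sum(~labels & preds)),
        tn=int(np.sum(~labels & ~preds)),
        fn=int(np.sum(labels & ~preds)),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def metrics(c: ConfusionCounts,
            recall_formula: Literal["standard", "as_printed"] = "standard"
            ) -> MetricReport:
    """Precision, accuracy, recall and F2 from a confusion table."""
    if recall_formula == "standard":
        recall = _ratio(c.tp, c.tp + c.fn)
    elif recall_formula == "as_printed":
        recall = _ratio(c.tp, c.tp + c.tn)
    else:
        raise ValueError(f"unknown recall formula {recall_formula!r}")
    return MetricReport(
        precision=_ratio(c.tp, c.tp + c.fp),
        accuracy=_ratio(c.tp + c.tn, c.total),
        recall=recall,
        f2=_ratio(5 * c.tp, 5 * c.tp + 4 * c.fn + c.fp),
    )


def single_feature_predictions(values: np.ndarray, M: float, N: float) -> np.ndarray:
    """Per-epoch exceedance of one feature over its own adaptive threshold.

    ``values[k]`` is compared against M*AVE + N*STD of ``values[k-4:k]``;
    the first four (warm-up) epochs never fire.
    """
    values = np.asarray(values, dtype=float)
    preds = np.zeros(values.size, dtype=bool)
    if values.size <= FIFO_DEPTH:
        return preds
    windows = np.lib.stride_tricks.sliding_window_view(values[:-1], FIFO_DEPTH)
    ave = windows.mean(axis=1)
    std = windows.std(axis=1)  # population form, divisor 4
    preds[FIFO_DEPTH:] = values[FIFO_DEPTH:] > M * ave + N * std
    return preds


@dataclass(frozen=True)
class GridResult:
    feature: str
    table: pd.DataFrame  # columns: feature, M, N, precision, accuracy, recall, f2, best
    best: tuple[int, int]

    def report(self, M: int, N: int) -> MetricReport:
        row = self.table[(self.table.M == M) & (self.table.N == N)].iloc[0]
        return MetricReport(
            precision=None if pd.isna(row.precision) else float(row.precision),
            accuracy=None if pd.isna(row.accuracy) else float(row.accuracy),
            recall=None if pd.isna(row.recall) else float(row.recall),
            f2=None if pd.isna(row.f2) else float(row.f2),
        )


def grid_search_values(values: np.ndarray, labels: Sequence[bool],
                       feature: str = "",
                       m_values: Iterable[int] = range(1, 6),
                       n_values: Iterable[int] = range(1, 6),
                       recall_formula: Literal["standard", "as_printed"] = "standard",
                       ) -> GridResult:
    """Grid-search (M, N) for one per-epoch feature series against labels.

    Metrics are tallied on post-warm-up epochs only (index >= 4).
    """
    m_values, n_values = list(m_values), list(n_values)
    if not m_values or not n_values:
        raise ValueError("empty (M, N) grid")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.size != values.size:
        raise ValueError("labels must cover every epoch")
    keep = np.arange(values.size) >= FIFO_DEPTH
    rows = []
    scored: dict[tuple[int, int], tuple] = {}
    for M in m_values:
        for N in n_values:
            preds = single_feature_predictions(values, M, N)
            rep = metrics(confusion(labels[keep], preds[keep]),
                          recall_formula=recall_formula)
            rows.append({"feature": feature, "M": M, "N": N,
                         "precision": rep.precision, "accuracy": rep.accuracy,
                         "recall": rep.recall, "f2": rep.f2})
            none = -1.0  # undefined metrics rank below any attained value
            scored[(M, N)] = (
                rep.f2 if rep.f2 is not None else none,
                rep.accuracy if rep.accuracy is not None else none,
                rep.recall if rep.recall is not None else none,
                -M, -N)
    best = max(scored, key=scored.get)
    table = pd.DataFrame(rows)
    table["best"] = (table.M == best[0]) & (table.N == best[1])
    return GridResult(feature=feature, table=table, best=best)


def grid_search(rec: Recording, labels: Sequence[bool], feature: str,
                m_values: Iterable[int] = range(1, 6),
                n_values: Iterable[int] = range(1, 6),
                cfg: RunConfig | None = None) -> GridResult:
    """Grid-search (M, N) for one named feature over a labelled recording."""
    cfg = cfg or RunConfig(fs=rec.fs)
    if feature not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {feature!r}; choose from {FEATURE_NAMES}")
    rows = epoch_matrix(rec, cfg.epoch_samples)
    values = feature_series(rows, feature, cfg.fs, cfg.mode,
                            cfg.slp_subwindow_ms)
    return grid_search_values(values, labels, feature=feature,
                              m_values=m_values, n_values=n_values)
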