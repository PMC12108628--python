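"""Class-specific and macro classification metrics for imbalanced problems.

The minority (hypotensive) class is the positive class.  Nine values are
reported per evaluation: recall / precision / F-score for the minority
class, for the majority class (computed on the swapped confusion table),
and their macro versions.  The macro F-score is composed from the macro
precision and macro recall (harmonic mean of the two macro averages), not
as the mean of the per-class F-scores; both conventions exist in the
literature and the composed form is the one reported here.

Zero-denominator cases (e.g. a classifier that never predicts the minority
class) yield a metric of 0 together with a ``degenerate`` flag instead of
NaN, so that fold averages stay defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

METRIC_NAMES = (
    "f1_m", "r_m", "p_m",
    "f1_min", "r_min", "p_min",
    "f1_may", "r_may", "p_may",
)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion table with the minority class as positive."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @classmethod
    def from_labels(cls, y_true, y_pred, positive: int = 1) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.shape != y_pred.shape:
            raise ValueError("label vectors must have equal length")
        pos_t = y_true == positive
        pos_p = y_pred == positive
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
        )

    def swapped(self) -> "ConfusionCounts":
        """The same table viewed with the majority class as positive."""
        return ConfusionCounts(tp=self.tn, fn=self.fp, fp=self.fn, tn=self.tp)


def _ratio(num: int, den: int) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


@dataclass(frozen=True)
class ClassMetrics:
    recall: float
    precision: float
    f1: float
    degenerate: bool  # some denominator was zero


def class_metrics(counts: ConfusionCounts, which: str = "minority") -> ClassMetrics:
    """Recall, precision and F-score for one class.

    ``which='majority'`` evaluates the swapped confusion table.
    """
    if which == "majority":
        counts = counts.swapped()
    elif which != "minority":
        raise ValueError("which must be 'minority' or 'majority'")
    if counts.tp + counts.fn == 0:
        raise ValueError("class has no true members")
    recall, deg_r = _ratio(counts.tp, counts.tp + counts.fn)
    precision, deg_p = _ratio(counts.tp, counts.tp + counts.fp)
    f1, deg_f = _harmonic(precision, recall)
    return ClassMetrics(recall, precision, f1, deg_r or deg_p or deg_f)


def _harmonic(p: float, r: float) -> tuple[float, bool]:
    if p + r == 0.0:
        return 0.0, True
    return 2.0 * p * r / (p + r), False


def macro_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(recall_macro, precision_macro, f1_macro).

    Unweighted two-class means; f1_macro is the harmonic mean of the two
    macro averages.
    """
    mi = class_metrics(counts, "minority")
    ma = class_metrics(counts, "majority")
    r_m = 0.5 * (mi.recall + ma.recall)
    p_m = 0.5 * (mi.precision + ma.precision)
    f1_m, _ = _harmonic(p_m, r_m)
    return r_m, p_m, f1_m


def macro_f1_classwise(counts: ConfusionCounts) -> float:
    """Mean of per-class F-scores (the other macro-F1 convention)."""
    mi = class_metrics(counts, "minority")
    ma = class_metrics(counts, "majority")
    return 0.5 * (mi.f1 + ma.f1)


def metric_bundle(counts: ConfusionCounts) -> dict[str, float]:
    """All nine reported metrics keyed by their table column names."""
    mi = class_metrics(counts, "minority")
    ma = class_metrics(counts, "majority")
    r_m, p_m, f1_m = macro_metrics(counts)
    return {
        "f1_m": f1_m, "r_m": r_m, "p_m": p_m,
        "f1_min": mi.f1, "r_min": mi.recall, "p_min": mi.precision,
        "f1_may": ma.f1, "r_may": ma.recall, "p_may": ma.precision,
    }


def tfs(mask) -> int:
    """Total features selected: the number of ones in a solution mask."""
    mask = np.asarray(mask)
    if mask.size and not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    return int(mask.sum())
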