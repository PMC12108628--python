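"""Nonparametric comparison battery for competing search configurations.

Repeated stochastic runs of several metaheuristic-classifier-objective
configurations produce a complete runs x configurations fitness matrix.
Configurations are compared in three gated stages:

1. Friedman omnibus test (tie-corrected, within-run mid-ranks) — is there
   any overall difference?
2. Nemenyi post hoc on the mean-rank differences (studentized-range
   distribution), applied only when the omnibus test rejects at 0.05 — which
   pairs differ?
3. One-sided Wilcoxon signed-rank tests on the Nemenyi-significant pairs —
   which member of each pair is better (smaller fitness)?

The gate order is enforced in code: requesting a later stage without the
earlier rejection is an error, not a silent computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


class GateError(RuntimeError):
    """A post hoc stage was requested without its prerequisite rejection."""


@dataclass
class ResultMatrix:
    """Complete runs x configurations fitness table."""

    values: np.ndarray
    config_names: list[str]
    objective_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (runs x configurations)")
        if np.isnan(self.values).any():
            raise ValueError("matrix must be complete (no missing cells)")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 runs")
        if self.values.shape[1] != len(self.config_names):
            raise ValueError("one name per configuration column")

    @classmethod
    def from_long(cls, frame: pd.DataFrame, objective_id: str | None = None,
                  value_col: str = "fitness") -> "ResultMatrix":
        """Build from a long-format table (run, configuration, objective, fitness)."""
        if objective_id is not None:
            frame = frame[frame["objective"] == objective_id]
        wide = frame.pivot(index="run", columns="configuration",
                           values=value_col)
        if wide.isna().any().any():
            raise ValueError("matrix must be complete (no missing cells)")
        return cls(wide.to_numpy(), list(wide.columns),
                   objective_id or "")


def _as_values(m) -> np.ndarray:
    return m.values if isinstance(m, ResultMatrix) else np.asarray(m, float)


def friedman_test(m) -> tuple[float, float]:
    """Tie-corrected Friedman chi-square statistic and p-value.

    Rows (runs) are ranked independently with mid-ranks for ties; a matrix
    whose columns are identical gives statistic 0 and p = 1.
    """
    values = _as_values(m)
    n, k = values.shape
    if k < 3:
        raise ValueError("Friedman test needs at least 3 configurations")
    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    if np.allclose(ranks, ranks[:, :1]):  # every row fully tied
        return 0.0, 1.0
    stat, p = stats.friedmanchisquare(*(values[:, j] for j in range(k)))
    return float(stat), float(p)


def friedman_mean_ranks(m) -> np.ndarray:
    values = _as_values(m)
    return np.apply_along_axis(stats.rankdata, 1, values).mean(axis=0)


def nemenyi_posthoc(m, friedman_p: float | None = None) -> pd.DataFrame:
    """Symmetric pairwise p-value matrix from the studentized-range law.

    Gated: only valid after a Friedman rejection.  If ``friedman_p`` is not
    supplied it is computed here; a non-significant omnibus result raises
    :class:`GateError`.
    """
    values = _as_values(m)
    names = (m.config_names if isinstance(m, ResultMatrix)
             else [f"c{j}" for j in range(values.shape[1])])
    if friedman_p is None:
        _, friedman_p = friedman_test(values)
    if friedman_p >= ALPHA:
        raise GateError(
            f"Friedman p = {friedman_p:.4g} >= {ALPHA}: the omnibus test "
            "did not reject, so the post hoc stage does not apply")
    n, k = values.shape
    mean_ranks = friedman_mean_ranks(values)
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    diff = np.abs(mean_ranks[:, None] - mean_ranks[None, :])
    q = diff / se * np.sqrt(2.0)
    p = stats.studentized_range.sf(q, k, np.inf)
    p = np.minimum(1.0, np.where(diff == 0.0, 1.0, p))
    np.fill_diagonal(p, 1.0)
    return pd.DataFrame(p, index=names, columns=names)


@dataclass(frozen=True)
class WilcoxonDecision:
    p_value: float | None
    decided: bool  # False when every paired difference is zero

    @property
    def significant(self) -> bool:
        return self.decided and self.p_value < ALPHA


def wilcoxon_less(a, b) -> WilcoxonDecision:
    """One-sided signed-rank test of "a stochastically less than b".

    For a minimization problem a small p-value means configuration ``a`` is
    better.  Zero differences are dropped before ranking; the exact null
    distribution (conditional on the observed ranks when ties are present)
    is used for up to 25 nonzero pairs, the tie-corrected normal
    approximation otherwise.  All-zero differences give no decision.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("samples must be paired (equal length)")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        return WilcoxonDecision(p_value=None, decided=False)
    method = "exact" if d.size <= 25 else "approx"
    res = stats.wilcoxon(d, alternative="less", zero_method="wilcox",
                         method=method)
    return WilcoxonDecision(p_value=float(res.pvalue), decided=True)


@dataclass
class PairwiseConclusion:
    better: str
    worse: str
    p_value: float


def summarize_wins(conclusions: list[PairwiseConclusion],
                   config_names: list[str]) -> pd.Series:
    """Per-configuration count of significant pairwise wins."""
    wins = pd.Series(0, index=list(config_names), dtype=int)
    for c in conclusions:
        wins[c.better] += 1
    return wins


@dataclass
class ComparisonReport:
    friedman_statistic: float
    friedman_p: float
    nemenyi: pd.DataFrame | None
    conclusions: list[PairwiseConclusion] = field(default_factory=list)
    wins: pd.Series | None = None


def compare_configurations(m: ResultMatrix, alpha: float = ALPHA) -> ComparisonReport:
    """Run the full three-stage battery with its gates.

    Wilcoxon tests are run in both directions for each Nemenyi-significant
    pair; a conclusion "A is better than B" is recorded when the one-sided
    test of A < B rejects at ``alpha``.
    """
    stat, p = friedman_test(m)
    report = ComparisonReport(friedman_statistic=stat, friedman_p=p,
                              nemenyi=None)
    if p >= alpha:
        return report
    nem = nemenyi_posthoc(m, friedman_p=p)
    report.nemenyi = nem
    names = m.config_names
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if nem.iloc[i, j] >= alpha:
                continue
            for x, y_ in ((i, j), (j, i)):
                dec = wilcoxon_less(m.values[:, x], m.values[:, y_])
                if dec.significant:
                    report.conclusions.append(PairwiseConclusion(
                        better=names[x], worse=names[y_],
                        p_value=dec.p_value))
    report.wins = summarize_wins(report.conclusions, names)
    return report


def report_tables(report: ComparisonReport) -> dict[str, pd.DataFrame]:
    """CSV-ready tables: omnibus summary, post hoc matrix, conclusions, wins."""
    out = {
        "friedman": pd.DataFrame(
            [{"statistic": report.friedman_statistic,
              "p_value": report.friedman_p,
              "significant": report.friedman_p < ALPHA}]),
    }
    if report.nemenyi is not None:
        out["nemenyi"] = report.nemenyi
    if report.conclusions:
        out["conclusions"] = pd.DataFrame(
            [{"conclusion": f"{c.better} is better than {c.worse}",
              "p_value": c.p_value,
              "p_value_rounded": round(c.p_value, 4)}
             for c in report.conclusions])
    if report.wins is not None:
        out["wins"] = report.wins.rename("wins").to_frame()
    return out
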