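"""Cohort-level statistics: exact 2x2 tests and grade comparisons."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["ContingencyTable2x2", "Exact2x2Result", "exact_2x2", "compare_grades"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) / (c, d); for the subtype x 1q use, rows are
    classical/basal and columns are 1q-gain/no-gain."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class Exact2x2Result:
    p_exact: float
    p_chisq: float
    p_chisq_yates: float
    odds_ratio: float


def exact_2x2(t: ContingencyTable2x2) -> Exact2x2Result:
    """Two-sided exact conditional test by full hypergeometric enumeration.

    All tables with the observed margins whose point probability does not
    exceed the observed table's contribute to p_exact.  Chi-square p-values
    (with and without Yates continuity correction) and the odds ratio
    (ad/bc, inf when bc = 0) are reported alongside.
    """
    if t.total == 0:
        warnings.warn("empty table: p = 1")
        return Exact2x2Result(1.0, 1.0, 1.0, float("nan"))
    row1, col1, n = t.a + t.b, t.a + t.c, t.total
    if row1 in (0, n) or col1 in (0, n):
        warnings.warn("zero margin: p = 1")
        or_ = _odds_ratio(t)
        return Exact2x2Result(1.0, 1.0, 1.0, or_)

    rv = sps.hypergeom(n, row1, col1)
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = rv.pmf(support)
    observed = rv.pmf(t.a)
    p_exact = float(pmf[pmf <= observed * (1 + 1e-9)].sum())
    p_exact = min(1.0, p_exact)

    table = np.array([[t.a, t.b], [t.c, t.d]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_chisq = float(sps.chi2_contingency(table, correction=False).pvalue)
        p_yates = float(sps.chi2_contingency(table, correction=True).pvalue)
    return Exact2x2Result(p_exact, p_chisq, p_yates, _odds_ratio(t))


def _odds_ratio(t: ContingencyTable2x2) -> float:
    if t.b * t.c == 0:
        return float("inf") if t.a * t.d > 0 else float("nan")
    return (t.a * t.d) / (t.b * t.c)


def compare_grades(
    values: Mapping[str, float],
    grades: Mapping[str, str],
    pairs: Mapping[str, tuple[str, str]] | None = None,
    low: str = "LG",
    high: str = "HG",
) -> dict:
    """HG-vs-LG comparison of a per-region statistic.

    Unpaired: Wilcoxon rank-sum over all regions of each grade.  Paired
    (when ``pairs`` gives one (LG, HG) region per patient): signed-rank test
    on per-patient deltas (HG − LG; positive = increase on progression).
    """
    lo_vals = [values[r] for r, g in sorted(grades.items()) if g == low and r in values]
    hi_vals = [values[r] for r, g in sorted(grades.items()) if g == high and r in values]
    report: dict = {
        "n_low": len(lo_vals),
        "n_high": len(hi_vals),
        "mean_low": float(np.mean(lo_vals)) if lo_vals else float("nan"),
        "mean_high": float(np.mean(hi_vals)) if hi_vals else float("nan"),
    }
    if len(lo_vals) >= 2 and len(hi_vals) >= 2:
        report["p_unpaired"] = float(
            sps.mannwhitneyu(hi_vals, lo_vals, alternative="two-sided").pvalue
        )
    else:
        report["p_unpaired"] = float("nan")

    deltas: dict[str, float] = {}
    if pairs:
        for patient, (r_lo, r_hi) in sorted(pairs.items()):
            if r_lo in values and r_hi in values:
                deltas[patient] = float(values[r_hi] - values[r_lo])
    report["deltas"] = deltas
    if deltas:
        d = np.array(list(deltas.values()))
        if np.all(d == 0):
            report["p_paired"] = 1.0
        else:
            report["p_paired"] = float(
                sps.wilcoxon(d, zero_method="zsplit", alternative="two-sided").pvalue
            )
    else:
        warnings.warn("no valid pairs: paired result omitted")
        report["p_paired"] = float("nan")
    return report
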