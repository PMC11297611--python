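"""Cohort summary statistics: Welch's t-test and the two-sided Fisher exact test.

These are the conventional case-vs-control comparisons for a demographics
table: Welch's unequal-variance t-test for continuous covariates (age,
serum titer) and Fisher's exact test for binary traits. The two-sided
Fisher p-value follows the SPSS/R convention — the sum of hypergeometric
point probabilities of all tables with the observed margins that are no
more probable than the observed one — computed by full enumeration over
the feasible range of the top-left cell.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "WelchSummary",
    "TestResult",
    "fisher_exact_two_sided",
    "welch_t_from_summary",
    "welch_t_from_samples",
    "format_count_percent",
    "table1_report",
]

#: Relative tolerance absorbing floating error when comparing hypergeometric
#: point probabilities against the observed table's probability.
_FISHER_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a..d: a/b = cases with/without the trait, c/d = controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative count, got {v}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_counts(cls, k_cases: int, n_cases: int, k_controls: int, n_controls: int):
        return cls(k_cases, n_cases - k_cases, k_controls, n_controls - k_controls)


@dataclass(frozen=True)
class WelchSummary:
    """Group summaries (x̄, s, n) for the unequal-variance t statistic."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int

    def __post_init__(self) -> None:
        if self.sd_a < 0 or self.sd_b < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_a < 2 or self.n_b < 2:
            raise ValueError("each group needs n >= 2")


@dataclass(frozen=True)
class TestResult:
    statistic: float | None
    df: float | None
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")


def fisher_exact_two_sided(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher exact p by enumeration of the hypergeometric support.

    With margins fixed, cell ``a`` ranges over max(0, r1-colsum2)..min(r1, c1)
    where r1 = a+b (cases) and c1 = a+c (trait carriers). The p-value sums
    the point probabilities of every feasible table whose probability does
    not exceed the observed table's (within a small relative tolerance).
    A zero margin makes the table degenerate; p is defined as 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        warnings.warn("degenerate 2x2 table (zero margin): p defined as 1.0")
        return TestResult(None, None, 1.0)
    dist = stats.hypergeom(n, c1, r1)  # draws r1 from n with c1 marked
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    p = float(pmf[pmf <= p_obs * (1.0 + _FISHER_RTOL)].sum())
    return TestResult(None, None, min(p, 1.0))


def welch_t_from_summary(s: WelchSummary) -> TestResult:
    """Welch's t with Welch–Satterthwaite degrees of freedom, two-sided p."""
    va = s.sd_a**2 / s.n_a
    vb = s.sd_b**2 / s.n_b
    se2 = va + vb
    if se2 == 0.0:
        # Degenerate: constant samples in both groups.
        df = float(s.n_a + s.n_b - 2)
        if s.mean_a == s.mean_b:
            return TestResult(0.0, df, 1.0)
        return TestResult(math.copysign(math.inf, s.mean_a - s.mean_b), df, 0.0)
    t = (s.mean_a - s.mean_b) / math.sqrt(se2)
    df = se2**2 / (va**2 / (s.n_a - 1) + vb**2 / (s.n_b - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TestResult(t, df, min(p, 1.0))


def welch_t_from_samples(values_a, values_b) -> TestResult:
    """Patient-level Welch test: summarize the samples, then delegate."""
    va = np.asarray(values_a, float)
    vb = np.asarray(values_b, float)
    if va.size < 2 or vb.size < 2:
        raise ValueError("each group needs at least 2 values")
    return welch_t_from_summary(
        WelchSummary(
            float(va.mean()), float(va.std(ddof=1)), int(va.size),
            float(vb.mean()), float(vb.std(ddof=1)), int(vb.size),
        )
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def format_count_percent(k: int, n: int) -> str:
    """Render "k/n (pct)" with the percentage rounded half away from zero."""
    pct = _round_half_away(100.0 * k / n) if n else 0
    return f"{k}/{n} ({pct})"


def table1_report(cohort, continuous_vars=(), binary_vars=()) -> "pd.DataFrame":
    """Case-vs-control summary rows in demographics-table layout.

    Binary rows (features of the cohort matrix) report k/n (%) per class
    with a Fisher exact p; continuous rows (columns of ``cohort.metadata``)
    report mean (SD) per class with a Welch p. p-values are formatted to
    three decimals.
    """
    import pandas as pd

    y = cohort.labels
    case_idx = y == 1
    ctrl_idx = y == 0
    rows = []
    for name in continuous_vars:
        if cohort.metadata is None or name not in cohort.metadata.columns:
            raise KeyError(f"unknown continuous variable {name!r}")
        vals = cohort.metadata[name].to_numpy(float)
        a, b = vals[case_idx], vals[ctrl_idx]
        res = welch_t_from_samples(a, b)
        rows.append(
            {
                "variable": name,
                "kind": "continuous",
                "cases": f"{a.mean():.1f} ({a.std(ddof=1):.1f})",
                "controls": f"{b.mean():.1f} ({b.std(ddof=1):.1f})",
                "p_value": f"{res.p_value:.3f}",
            }
        )
    for name in binary_vars:
        if name not in cohort.feature_names:
            raise KeyError(f"unknown binary variable {name!r}")
        col = cohort.matrix[:, cohort.feature_names.index(name)]
        ka, na = int(col[case_idx].sum()), int(case_idx.sum())
        kc, nc = int(col[ctrl_idx].sum()), int(ctrl_idx.sum())
        res = fisher_exact_two_sided(ContingencyTable2x2.from_counts(ka, na, kc, nc))
        rows.append(
            {
                "variable": name,
                "kind": "binary",
                "cases": format_count_percent(ka, na),
                "controls": format_count_percent(kc, nc),
                "p_value": f"{res.p_value:.3f}",
            }
        )
    return pd.DataFrame(rows, columns=["variable", "kind", "cases", "controls", "p_value"])
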