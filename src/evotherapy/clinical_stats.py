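"""Interim trial statistics: exact contingency tests and cumulative-dose
summaries for the 11-patient adaptive-therapy cohort.

The contingency tests compare progression counts between cohorts with the
one-sided Fisher exact test, computed here by exact rational summation of
hypergeometric point masses (stdlib ``fractions``), so the p-values carry
no floating-point error.  The historic comparison table splits the 546
control patients 273/273 around their published median time to PSA
progression; with one of 11 trial patients below that median the one-sided
p-value is 0.006.

The cohort fixture mirrors the trial's interim disease-status table
(subject id, Gleason score, metastatic site, pre-abiraterone PSA, and the
cumulative abiraterone dose as a percentage of standard-of-care dosing).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from math import comb, sqrt
from typing import NamedTuple

import pandas as pd
from scipy.stats import norm

__all__ = [
    "TwoByTwoTable",
    "TRIAL_VS_HISTORIC",
    "TRIAL_VS_CONTEMPORANEOUS",
    "load_trial_cohort",
    "fisher_exact_leq",
    "cohort_dose_summary",
    "poisson_mean_comparison",
]


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts (a, b / c, d): rows are cohorts, columns outcome/no-outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(v) != v or v < 0 for v in counts):
            raise ValueError("counts must be non-negative integers")
        if sum(counts) == 0:
            raise ValueError("at least one count must be positive")

    @property
    def degenerate(self) -> bool:
        """A zero row or column margin makes the test uninformative."""
        return (self.a + self.b == 0 or self.c + self.d == 0
                or self.a + self.c == 0 or self.b + self.d == 0)


#: 1 of 11 trial patients vs. 273 of 546 historic controls with PSA
#: progression before the historic median time (11.1 months).
TRIAL_VS_HISTORIC = TwoByTwoTable(1, 10, 273, 273)

#: 1 of 11 trial patients vs. 14 of 16 contemporaneous standard-of-care
#: patients with radiographic progression.
TRIAL_VS_CONTEMPORANEOUS = TwoByTwoTable(1, 10, 14, 2)


def _hypergeom_cdf(table: TwoByTwoTable, upper: bool) -> Fraction:
    n_total = table.a + table.b + table.c + table.d
    k_col = table.a + table.c
    n_row = table.a + table.b
    denom = comb(n_total, n_row)
    lo = max(0, n_row - (n_total - k_col))
    hi = min(n_row, k_col)
    ks = range(table.a, hi + 1) if upper else range(lo, table.a + 1)
    return sum(
        (Fraction(comb(k_col, k) * comb(n_total - k_col, n_row - k), denom)
         for k in ks),
        Fraction(0),
    )


def fisher_exact_leq(table: TwoByTwoTable, upper: bool = False,
                     exact: bool = False):
    """One-sided Fisher exact p-value P(X <= a) for the top-left count
    under the hypergeometric null (P(X >= a) with ``upper=True``).

    Computed by exact rational summation; pass ``exact=True`` for the
    :class:`fractions.Fraction` instead of a float.  Degenerate margins
    give p = 1 (see :attr:`TwoByTwoTable.degenerate`).
    """
    if table.degenerate:
        p = Fraction(1)
    else:
        p = _hypergeom_cdf(table, upper=upper)
    return p if exact else float(p)


def load_trial_cohort() -> pd.DataFrame:
    """The packaged 11-patient trial cohort table."""
    with resources.files("evotherapy.data").joinpath("trial_cohort.csv").open() as fh:
        return pd.read_csv(fh)


class DoseSummary(NamedTuple):
    mean_pct: int
    mean_pct_unrounded: float
    n: int


def cohort_dose_summary(fixture: pd.DataFrame | None = None) -> DoseSummary:
    """Arithmetic mean of the cohort's per-patient cumulative dose
    percentages, rounded to integer percent for reporting (the unrounded
    value is also returned)."""
    if fixture is None:
        fixture = load_trial_cohort()
    doses = fixture["dose_pct"].to_numpy(dtype=float)
    if doses.size == 0:
        raise ValueError("cohort is empty")
    mean = float(doses.mean())
    return DoseSummary(mean_pct=round(mean), mean_pct_unrounded=mean,
                       n=int(doses.size))


class PoissonComparison(NamedTuple):
    z: float
    p_value: float


def poisson_mean_comparison(observed_mean: float, n: int,
                            reference_mean: float) -> PoissonComparison:
    """Normal-approximation comparison of an observed mean event time
    against a reference mean, z = (obs - ref) / sqrt(ref / n), with the
    one-sided p-value for the alternative "observed exceeds reference".

    This is this package's fixed operationalization of a Poisson-rate mean
    comparison (the sampling variance of a mean of n exponential/Poisson-
    scale times is taken as ref/n); it is deliberately simple and is
    reported alongside, not instead of, the exact contingency tests.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if observed_mean <= 0 or reference_mean <= 0:
        raise ValueError("means must be positive")
    z = (observed_mean - reference_mean) / sqrt(reference_mean / n)
    return PoissonComparison(z=float(z), p_value=float(norm.sf(z)))
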