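"""Reclassification accounting: adjusted tiers versus the CALC tier.

Movement categories follow the certification semantics (tier 1 best): an OPO
"moves into a lower tier" when its adjusted tier number is smaller (better)
than its CALC tier; "into tier 1" requires CALC tier 2 or 3; "out of tier 3"
requires CALC tier 3. An OPO moving 3 -> 1 counts in both "out of tier 3" and
"into tier 1". Percentages are carried at full precision and display-rounded
to one decimal (two below 1%).

The Wilcoxon signed-rank rate-shift test drops zero differences, uses
midranks for tied absolute differences, and computes the exact conditional
null distribution by a generating-function convolution for n <= 25, switching
to the normal approximation with continuity and tie correction for larger n.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComparisonError, ComputationError

__all__ = [
    "ReclassSummary", "ShiftTestResult",
    "reclassification_rate", "movement_categories", "summarize_reclassification",
    "cumulative_change", "rank_reassignment", "rate_shift_test",
    "percent",
]


def percent(k: float, n: float) -> float:
    """100 * k / n at full precision (display rounding happens at output)."""
    if n == 0:
        raise ComputationError("percentage of an empty set is undefined")
    return 100.0 * k / n


def _paired(calc_tiers: pd.Series, adjusted_tiers: pd.Series) -> pd.DataFrame:
    calc = pd.Series(calc_tiers)
    adj = pd.Series(adjusted_tiers)
    if set(calc.index) != set(adj.index):
        raise ComparisonError("CALC and adjusted tier tables cover different OPO sets")
    if calc.index.has_duplicates or adj.index.has_duplicates:
        raise ComparisonError("duplicate OPO entries in a tier table")
    return pd.DataFrame({"calc": calc, "adj": adj.reindex(calc.index)})


def reclassification_rate(calc_tiers: pd.Series, adjusted_tiers: pd.Series) -> float:
    """Percentage of OPOs whose adjusted tier differs from the CALC tier."""
    d = _paired(calc_tiers, adjusted_tiers)
    return percent(int((d["calc"] != d["adj"]).sum()), len(d))


@dataclass
class ReclassSummary:
    """Movement-category counts for one (year, variant) comparison."""

    n_opos: int
    n_changed: int
    pct_changed: float
    no_change: int
    into_lower_tier: int      # adjusted tier number < CALC (improvement)
    into_higher_tier: int     # adjusted tier number > CALC (demotion)
    into_tier1: int           # CALC in {2,3} and adjusted == 1
    out_of_tier1: int         # CALC == 1 and adjusted in {2,3}
    into_tier3: int           # CALC in {1,2} and adjusted == 3
    out_of_tier3: int         # CALC == 3 and adjusted in {1,2}

    def as_dict(self) -> dict:
        return asdict(self)


def movement_categories(calc_tiers: pd.Series, adjusted_tiers: pd.Series) -> ReclassSummary:
    """Count every movement category; an OPO can fall in several (e.g. 3 -> 1
    is both out-of-tier-3 and into-tier-1)."""
    d = _paired(calc_tiers, adjusted_tiers)
    calc, adj = d["calc"], d["adj"]
    changed = calc != adj
    return ReclassSummary(
        n_opos=len(d),
        n_changed=int(changed.sum()),
        pct_changed=percent(int(changed.sum()), len(d)),
        no_change=int((~changed).sum()),
        into_lower_tier=int((adj < calc).sum()),
        into_higher_tier=int((adj > calc).sum()),
        into_tier1=int((calc.isin([2, 3]) & (adj == 1)).sum()),
        out_of_tier1=int(((calc == 1) & adj.isin([2, 3])).sum()),
        into_tier3=int((calc.isin([1, 2]) & (adj == 3)).sum()),
        out_of_tier3=int(((calc == 3) & adj.isin([1, 2])).sum()),
    )


def _tier_series(tiers_df: pd.DataFrame, year: int, variant: str) -> pd.Series:
    sub = tiers_df[
        (tiers_df["year"] == year)
        & (tiers_df["tier_variant"] == variant)
        & tiers_df["defined"]
    ]
    return sub.set_index("opo")["tier"].astype(int)


def summarize_reclassification(
    tiers_df: pd.DataFrame, variants=("age", "adi", "age_adi"), years=None
) -> pd.DataFrame:
    """One ReclassSummary row per (year, variant) against the same-year CALC tier."""
    if years is None:
        years = sorted(tiers_df["year"].unique())
    rows = []
    for variant in variants:
        for year in years:
            calc = _tier_series(tiers_df, year, "calc")
            adj = _tier_series(tiers_df, year, variant)
            summary = movement_categories(calc, adj)
            rows.append({"year": int(year), "variant": variant, **summary.as_dict()})
    return pd.DataFrame(rows)


def cumulative_change(tiers_df: pd.DataFrame, variant: str, years=None) -> float:
    """Percentage of OPOs whose variant tier differs from the same-year CALC
    tier in at least one of the given years."""
    if years is None:
        years = sorted(tiers_df["year"].unique())
    changed: set = set()
    opo_sets = []
    for year in years:
        calc = _tier_series(tiers_df, year, "calc")
        adj = _tier_series(tiers_df, year, variant)
        d = _paired(calc, adj)
        opo_sets.append(frozenset(d.index))
        changed |= set(d.index[d["calc"] != d["adj"]])
    if len(set(opo_sets)) > 1:
        raise ComparisonError("OPO set differs across years in cumulative comparison")
    return percent(len(changed), len(opo_sets[0]))


def rank_reassignment(tiers_df: pd.DataFrame, variant: str, years=None) -> dict:
    """Share of OPOs whose per-measure group differs from the CALC-variant
    group in at least one year, separately for donation and transplant."""
    if years is None:
        years = sorted(tiers_df["year"].unique())
    out = {}
    for measure, col in (("donation", "donation_group"), ("transplant", "transplant_group")):
        changed: set = set()
        n = None
        opo_sets = []
        for year in years:
            calc = tiers_df[(tiers_df["year"] == year)
                            & (tiers_df["tier_variant"] == "calc")
                            & tiers_df["defined"]].set_index("opo")[col]
            adj = tiers_df[(tiers_df["year"] == year)
                           & (tiers_df["tier_variant"] == variant)
                           & tiers_df["defined"]].set_index("opo")[col]
            d = _paired(calc, adj)
            n = len(d)
            opo_sets.append(frozenset(d.index))
            changed |= set(d.index[d["calc"] != d["adj"]])
        if len(set(opo_sets)) > 1:
            raise ComparisonError("OPO set differs across years in rank comparison")
        out[measure] = percent(len(changed), n)
    return out


@dataclass
class ShiftTestResult:
    statistic: float          # W+, sum of positive-difference ranks
    pvalue: float
    median_abs_diff: float
    n: int                    # pairs remaining after dropping zero differences
    method: str               # "exact", "approx", or "degenerate"


def _wilcoxon_exact_p(w_plus: float, ranks2: np.ndarray) -> float:
    """Exact two-sided p by convolving the signed-rank generating function.

    ``ranks2`` holds doubled midranks (integers even with ties); the null
    distribution is over all 2^n sign assignments, conditional on the
    observed tie pattern.
    """
    total = int(ranks2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    w2 = int(round(2 * w_plus))
    cdf = np.cumsum(pmf)
    p_le = float(cdf[w2])
    p_ge = float(1.0 - (cdf[w2 - 1] if w2 > 0 else 0.0))
    return min(1.0, 2.0 * min(p_le, p_ge))


def rate_shift_test(calc_rates, adjusted_rates, method: str = "auto") -> ShiftTestResult:
    """Wilcoxon signed-rank test of paired rate differences plus median |diff|.

    ``method``: "exact" (n <= 25 enumeration), "approx" (normal with
    continuity and tie correction), or "auto" (exact when n <= 25). All-zero
    differences yield a degenerate result with p = 1.
    """
    x = np.asarray(calc_rates, dtype=float)
    y = np.asarray(adjusted_rates, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ComparisonError("rate_shift_test needs equal-length paired vectors")
    diffs = y - x
    med_abs = float(np.median(np.abs(diffs)))
    nz = diffs[diffs != 0]
    n = len(nz)
    if n == 0:
        return ShiftTestResult(0.0, 1.0, med_abs, 0, "degenerate")
    if n < 5:
        raise ComputationError("rate_shift_test needs >= 5 nonzero differences")
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    if method == "auto":
        method = "exact" if n <= 25 else "approx"
    if method == "exact":
        ranks2 = np.round(2 * ranks).astype(np.int64)
        p = _wilcoxon_exact_p(w_plus, ranks2)
    elif method == "approx":
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_corr = float(((counts**3 - counts).sum())) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
        d = w_plus - mean
        z = (d - 0.5 * np.sign(d)) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        raise ComputationError(f"unknown method {method!r}")
    return ShiftTestResult(w_plus, float(min(p, 1.0)), med_abs, n, method)
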