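"""Prior-year thresholds and three-tier performance assignment.

Each year every OPO is placed into tier 1 (best) to 3 (worst) by comparing
the one-sided 95% UCL of its donation measure and of its transplant measure
against the previous year's median and top-25% (75th percentile) thresholds
of the corresponding point rates:

* group 1 if UCL >= top-25% threshold,
* group 2 if UCL >= median,
* group 3 otherwise,

and the tier is the worse (numerically larger) of the two measure groups.
Meeting a threshold exactly suffices (``>=`` convention).

Four tier variants pair the measures differently; the OPO configured as HIOP
(the Hawaii OPO, whose CMS transplant measure is kidney-only) swaps the
transplant measure for the kidney transplant rate at the variant-specific
adjustment level:

=========  ==================  =========================  ================
variant    donation measure    transplant measure         HIOP kidney
=========  ==================  =========================  ================
calc       raw                 age-adjusted organ         raw
age        age-adjusted        age-adjusted organ         age-adjusted
adi        ADI-adjusted        age+ADI-adjusted organ     ADI-adjusted
age_adi    age+ADI-adjusted    age+ADI-adjusted organ     age+ADI-adjusted
=========  ==================  =========================  ================

Thresholds default to the SAS-style averaged-inverted-CDF percentile rule
(the value averaged across the two straddling order statistics when the rank
is integral); the rule is configurable because tier flips can hinge on it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AssignmentError, ThresholdError

__all__ = [
    "TIER_VARIANTS", "VARIANT_MEASURES", "DEFAULT_PERCENTILE_RULE",
    "compute_thresholds", "threshold_table",
    "measure_group", "assign_tier", "assign_tiers_variant", "assign_all_tiers",
]

TIER_VARIANTS = ("calc", "age", "adi", "age_adi")

#: tier variant -> (donation rate variant, organ-transplant rate variant,
#:                  HIOP kidney-transplant rate variant)
VARIANT_MEASURES = {
    "calc": ("raw", "age", "raw"),
    "age": ("age", "age", "age"),
    "adi": ("adi", "age_adi", "adi"),
    "age_adi": ("age_adi", "age_adi", "age_adi"),
}

DEFAULT_PERCENTILE_RULE = "averaged_inverted_cdf"


def compute_thresholds(rates, rule: str = DEFAULT_PERCENTILE_RULE) -> tuple[float, float]:
    """(median, top-25%) thresholds of the point rates across OPOs.

    Needs at least two defined rates; NaN rates (zero-potential OPOs) must be
    removed by the caller.
    """
    arr = np.asarray(rates, dtype=float)
    arr = arr[np.isfinite(arr)]
    if len(arr) < 2:
        raise ThresholdError("thresholds need at least 2 defined rates")
    t_median = float(np.percentile(arr, 50, method=rule))
    t_top25 = float(np.percentile(arr, 75, method=rule))
    return t_median, t_top25


def threshold_table(
    rates_df: pd.DataFrame, years=None, rule: str = DEFAULT_PERCENTILE_RULE
) -> pd.DataFrame:
    """Thresholds for every (source_year, measure, variant) in a rate table."""
    if years is None:
        years = sorted(rates_df["year"].unique())
    rows = []
    for year in years:
        sub = rates_df[(rates_df["year"] == year) & rates_df["defined"]]
        for (measure, variant), grp in sub.groupby(["measure", "variant"], sort=True):
            t_median, t_top25 = compute_thresholds(grp["rate"].to_numpy(), rule)
            rows.append(dict(source_year=int(year), measure=measure, variant=variant,
                             t_median=t_median, t_top25=t_top25, rule=rule))
    return pd.DataFrame(rows)


def measure_group(ucl: float, t_median: float, t_top25: float) -> int:
    """1 if UCL >= top-25% threshold, 2 if >= median, else 3."""
    if ucl >= t_top25:
        return 1
    if ucl >= t_median:
        return 2
    return 3


def assign_tier(donation_group: int, transplant_group: int) -> int:
    """The worse (numerically larger) of the two measure groups."""
    return max(int(donation_group), int(transplant_group))


def _lookup_thresholds(thresholds: pd.DataFrame, source_year: int, measure: str, variant: str):
    row = thresholds[
        (thresholds["source_year"] == source_year)
        & (thresholds["measure"] == measure)
        & (thresholds["variant"] == variant)
    ]
    if len(row) != 1:
        raise AssignmentError(
            f"missing prior-year thresholds for ({measure}, {variant}) from {source_year}"
        )
    return float(row["t_median"].iloc[0]), float(row["t_top25"].iloc[0])


def assign_tiers_variant(
    rates_df: pd.DataFrame,
    thresholds: pd.DataFrame,
    year: int,
    tier_variant: str,
    hiop_code: str | None = None,
) -> pd.DataFrame:
    """Tier assignments for one year under one tier variant.

    ``rates_df`` is the tidy table from
    :func:`~opometrics.performance_metrics.compute_all_measures`;
    ``thresholds`` must contain year-1 entries for the measures the variant
    uses. OPOs with undefined rates are flagged (tier NaN), not defaulted to
    tier 3.
    """
    if tier_variant not in VARIANT_MEASURES:
        raise AssignmentError(f"unknown tier variant {tier_variant!r}")
    don_var, tx_var, hiop_var = VARIANT_MEASURES[tier_variant]
    prior = int(year) - 1
    thr_don = _lookup_thresholds(thresholds, prior, "donation", don_var)
    thr_tx = _lookup_thresholds(thresholds, prior, "organ_transplant", tx_var)
    thr_kid = (
        _lookup_thresholds(thresholds, prior, "kidney_transplant", hiop_var)
        if hiop_code is not None else None
    )

    sub = rates_df[rates_df["year"] == year]
    don = sub[(sub["measure"] == "donation") & (sub["variant"] == don_var)].set_index("opo")
    tx = sub[(sub["measure"] == "organ_transplant") & (sub["variant"] == tx_var)].set_index("opo")
    kid = sub[(sub["measure"] == "kidney_transplant") & (sub["variant"] == hiop_var)].set_index("opo")

    rows = []
    for opo in don.index.sort_values():
        use_kidney = hiop_code is not None and opo == hiop_code
        d_row = don.loc[opo]
        t_row = kid.loc[opo] if use_kidney else tx.loc[opo]
        t_thr = thr_kid if use_kidney else thr_tx
        if not (d_row["defined"] and t_row["defined"]):
            rows.append(dict(opo=opo, year=int(year), tier_variant=tier_variant,
                             donation_group=np.nan, transplant_group=np.nan,
                             tier=np.nan, used_kidney_override=use_kidney,
                             defined=False))
            continue
        dg = measure_group(float(d_row["ucl95"]), *thr_don)
        tg = measure_group(float(t_row["ucl95"]), *t_thr)
        rows.append(dict(opo=opo, year=int(year), tier_variant=tier_variant,
                         donation_group=dg, transplant_group=tg,
                         tier=assign_tier(dg, tg), used_kidney_override=use_kidney,
                         defined=True))
    return pd.DataFrame(rows)


def assign_all_tiers(
    rates_df: pd.DataFrame,
    eval_years,
    tier_variants=TIER_VARIANTS,
    hiop_code: str | None = None,
    rule: str = DEFAULT_PERCENTILE_RULE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tier table for every evaluation year x variant, plus the thresholds used.

    Thresholds for year y are computed exclusively from year y-1 rates.
    """
    source_years = sorted({int(y) - 1 for y in eval_years})
    thresholds = threshold_table(rates_df, years=source_years, rule=rule)
    frames = [
        assign_tiers_variant(rates_df, thresholds, year, variant, hiop_code)
        for year in eval_years
        for variant in tier_variants
    ]
    return pd.concat(frames, ignore_index=True), thresholds
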