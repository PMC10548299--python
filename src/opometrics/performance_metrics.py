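"""CALC donor potential, crude and indirectly standardized rates, and
one-sided 95% upper confidence limits.

Donor potential D is the count of inpatient deaths aged 75 or younger whose
primary cause is consistent with organ donation. Three measures are computed
per OPO-year, each expressed as a percentage of D:

* ``donation`` — organ donors (a true proportion, O <= D);
* ``organ_transplant`` / ``kidney_transplant`` — organs (kidneys)
  transplanted; these are counts per potential and may exceed 100%.

Indirect standardization follows the observed/expected construction: national
stratum-specific rates ``r_s = sum O_s / sum D_s`` give each OPO an expected
count ``E = sum D_s r_s``; the adjusted rate is ``100 * (O/E) * R_nat`` where
``R_nat`` is the national crude rate. Adjustment variants differ only in the
stratification: ``raw`` (single stratum), ``age``, ``adi``, ``age_adi``.

The one-sided 95% UCL of the donation proportion defaults to the exact
Clopper–Pearson bound (Beta(O+1, D−O) 95th percentile); Wilson and Wald
alternatives are provided for sensitivity. Transplant measures are count-type
rather than proportion-type, so their bound uses the exact one-sided Poisson
(gamma) bound on the count divided by D. Adjusted UCLs pass the crude bound
through the same O/E scaling as the point rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, ConfigurationError
from .registry_io import assign_opo_frame, resolve_adi_quintile

__all__ = [
    "DEFAULT_AGE_BINS", "AGE_MAX", "MEASURES", "VARIANTS",
    "StratumScheme", "NationalRates",
    "identify_donor_potential", "build_stratified_counts",
    "national_rates", "expected_events", "standardized_rate",
    "ucl95", "ucl95_standardized", "compute_measures", "compute_all_measures",
]

AGE_MAX = 75
DEFAULT_AGE_BINS = ((0, 15), (15, 25), (25, 40), (40, 55), (55, 65), (65, 76))
MEASURES = ("donation", "organ_transplant", "kidney_transplant")
VARIANTS = ("raw", "age", "adi", "age_adi")
_EVENT_COL = {"donation": "donors", "organ_transplant": "organs",
              "kidney_transplant": "kidneys"}
#: donation is a proportion of potential; transplant measures are counts
_CI_SCALE = {"donation": "binomial", "organ_transplant": "poisson",
             "kidney_transplant": "poisson"}
_Z95 = float(stats.norm.ppf(0.95))


@dataclass(frozen=True)
class StratumScheme:
    """Stratification used for standardization.

    ``mode`` selects the stratum index set: ``none`` (single stratum, i.e. no
    adjustment), ``age``, ``adi``, or ``age_adi``. Age bins must be disjoint,
    exhaustive over [0, 75], lower-inclusive/upper-exclusive with the last bin
    closed at 75.
    """

    mode: str = "age_adi"
    age_bins: tuple = DEFAULT_AGE_BINS

    def __post_init__(self):
        if self.mode not in ("none", "age", "adi", "age_adi"):
            raise ConfigurationError(f"unknown stratification mode {self.mode!r}")
        bins = self.age_bins
        if bins[0][0] != 0 or bins[-1][1] != AGE_MAX + 1:
            raise ConfigurationError("age bins must cover 0 through 75 inclusive")
        for (lo, hi), (lo2, _) in zip(bins, bins[1:]):
            if hi != lo2 or hi <= lo:
                raise ConfigurationError("age bins must be contiguous and increasing")

    @property
    def n_strata(self) -> int:
        return {"none": 1, "age": len(self.age_bins), "adi": 5,
                "age_adi": 5 * len(self.age_bins)}[self.mode]

    def labels(self, age: np.ndarray, adi_quintile: np.ndarray) -> np.ndarray:
        """Integer stratum index for each record (age must be <= 75)."""
        if self.mode == "none":
            return np.zeros(len(age), dtype=np.int64)
        edges = np.asarray([b[0] for b in self.age_bins[1:]])
        bin_idx = np.digitize(np.asarray(age), edges)
        q = np.asarray(adi_quintile, dtype=np.int64)
        if self.mode == "age":
            return bin_idx.astype(np.int64)
        if self.mode == "adi":
            return q - 1
        return bin_idx.astype(np.int64) * 5 + (q - 1)


def identify_donor_potential(deaths: pd.DataFrame, age_max: int = AGE_MAX) -> pd.DataFrame:
    """CALC donor potential: inpatient AND donation-consistent cause AND age <= 75."""
    mask = deaths["inpatient"] & deaths["calc_cause"] & (deaths["age"] <= age_max)
    return deaths.loc[mask]


def resolve_cohort(
    deaths: pd.DataFrame,
    donors: pd.DataFrame,
    crosswalk: pd.DataFrame,
    quintiles: pd.Series,
    *,
    drop_invalid: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter to CALC potential and attach OPO and ADI quintile once.

    Deaths are assigned to the OPO of the death county; donors to the OPO of
    the hospital county. Both inherit the ADI quintile of the residence
    county with death/hospital-county fallback.
    """
    calc = identify_donor_potential(deaths).copy()
    opo, _ = assign_opo_frame(calc, crosswalk, "county_of_death", drop_invalid=drop_invalid)
    calc = calc.loc[opo.notna()]
    calc["opo"] = opo.loc[calc.index]
    calc["adi_quintile"] = resolve_adi_quintile(
        calc, quintiles, "county_of_residence", "county_of_death"
    )
    ev = donors.copy()
    if len(ev):
        opo_d, _ = assign_opo_frame(ev, crosswalk, "hospital_county", drop_invalid=drop_invalid)
        ev = ev.loc[opo_d.notna()]
        ev["opo"] = opo_d.loc[ev.index]
        ev["adi_quintile"] = resolve_adi_quintile(
            ev, quintiles, "residence_county", "hospital_county"
        )
    return calc, ev


def _stratified_counts_resolved(
    calc: pd.DataFrame, ev: pd.DataFrame, scheme: StratumScheme
) -> tuple[pd.DataFrame, pd.DataFrame]:
    calc = calc.assign(
        stratum=scheme.labels(calc["age"].to_numpy(), calc["adi_quintile"].to_numpy())
    )
    potentials = (
        calc.groupby(["opo", "year", "stratum"], sort=True)
        .size().rename("D").reset_index()
    )
    if len(ev):
        ev = ev.assign(
            stratum=scheme.labels(ev["age"].to_numpy(), ev["adi_quintile"].to_numpy())
        )
        events = (
            ev.groupby(["opo", "year", "stratum"], sort=True)
            .agg(donors=("donor_id", "size"),
                 organs=("organs_transplanted", "sum"),
                 kidneys=("kidneys_transplanted", "sum"))
            .reset_index()
        )
    else:
        events = pd.DataFrame(columns=["opo", "year", "stratum", "donors", "organs", "kidneys"])
    return potentials, events


def build_stratified_counts(
    deaths: pd.DataFrame,
    donors: pd.DataFrame,
    crosswalk: pd.DataFrame,
    quintiles: pd.Series,
    scheme: StratumScheme,
    *,
    drop_invalid: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per (opo, year, stratum) potential and event counts.

    Returns ``(potentials, events)``: potentials has a ``D`` column; events
    has ``donors``, ``organs``, ``kidneys``. See :func:`resolve_cohort` for
    the OPO/ADI attribution rules.
    """
    calc, ev = resolve_cohort(deaths, donors, crosswalk, quintiles, drop_invalid=drop_invalid)
    return _stratified_counts_resolved(calc, ev, scheme)


@dataclass
class NationalRates:
    """National stratum-specific rates and crude rates for one year."""

    year: int
    r: pd.DataFrame          # index: stratum; columns: donors, organs, kidneys
    R_nat: dict              # measure event column -> national crude rate
    flagged_strata: list     # strata with zero national potential but events


def national_rates(potentials: pd.DataFrame, events: pd.DataFrame, year: int) -> NationalRates:
    """Stratum rates r_s = sum O_s / sum D_s pooled over OPOs for one year."""
    pot = potentials[potentials["year"] == year]
    ev = events[events["year"] == year]
    D_s = pot.groupby("stratum")["D"].sum()
    if D_s.sum() == 0:
        raise ComputationError(f"national donor potential is zero in {year}")
    O_s = ev.groupby("stratum")[["donors", "organs", "kidneys"]].sum()
    all_strata = D_s.index.union(O_s.index)
    D_s = D_s.reindex(all_strata, fill_value=0)
    O_s = O_s.reindex(all_strata, fill_value=0)
    flagged = list(all_strata[(D_s == 0) & (O_s.sum(axis=1) > 0)])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = O_s.div(D_s, axis=0)
    r[D_s == 0] = 0.0
    R_nat = {c: float(O_s[c].sum() / D_s.sum()) for c in ("donors", "organs", "kidneys")}
    return NationalRates(year=int(year), r=r, R_nat=R_nat, flagged_strata=flagged)


def expected_events(D_s: pd.Series, r_s: pd.Series) -> float:
    """E = sum_s D_s * r_s with strata aligned by index.

    Strata occupied by the OPO but absent from the national rate table
    contribute zero (they are already flagged by :func:`national_rates`).
    """
    r = r_s.reindex(D_s.index, fill_value=0.0)
    return float((D_s * r).sum())


def standardized_rate(O: float, E: float, R_nat: float) -> float:
    """Indirectly standardized rate, percent of potential: 100 * (O/E) * R_nat."""
    if E == 0:
        if O == 0:
            return 0.0
        raise ComputationError("standardized rate undefined: E = 0 with O > 0")
    return 100.0 * (O / E) * R_nat


def _ucl_prop(O, D, method: str, scale: str):
    """One-sided 95% upper bound on events-per-potential (proportion scale)."""
    O = np.asarray(O, dtype=float)
    D = np.asarray(D, dtype=float)
    if (D <= 0).any():
        raise ComputationError("UCL undefined for D = 0")
    p = O / D
    if scale == "binomial":
        if method == "exact":
            with np.errstate(invalid="ignore"):
                u = stats.beta.ppf(0.95, O + 1, D - O)
            u = np.where(O >= D, 1.0, u)
        elif method == "wilson":
            z2 = _Z95**2
            u = (p + z2 / (2 * D) + _Z95 * np.sqrt(p * (1 - p) / D + z2 / (4 * D**2))) / (1 + z2 / D)
        elif method == "wald":
            u = np.clip(p + _Z95 * np.sqrt(p * (1 - p) / D), 0.0, 1.0)
        else:
            raise ConfigurationError(f"unknown CI method {method!r}")
    elif scale == "poisson":
        if method == "exact":
            u = stats.gamma.ppf(0.95, O + 1) / D
        elif method in ("wilson", "wald"):
            u = p + _Z95 * np.sqrt(np.maximum(p, 0) / D)
        else:
            raise ConfigurationError(f"unknown CI method {method!r}")
    else:
        raise ConfigurationError(f"unknown CI scale {scale!r}")
    return u


def ucl95(O, D, method: str = "exact", scale: str = "binomial"):
    """One-sided 95% upper confidence limit as a percent of donor potential.

    ``scale='binomial'`` treats O as a proportion numerator (donation);
    ``scale='poisson'`` treats O as a count per D potentials (transplants).
    The exact binomial bound is the Clopper–Pearson one-sided limit, i.e. the
    95th percentile of Beta(O+1, D−O), which satisfies
    ``P[X <= O | p = UCL] = 0.05`` for O < D.
    """
    return 100.0 * _ucl_prop(O, D, method, scale)


def ucl95_standardized(O, D, E, R_nat, method: str = "exact", scale: str = "binomial"):
    """Crude UCL passed through the O/E standardization scaling.

    ``UCL_adj = 100 * UCL_prop(O, D) * (D / E) * R_nat``; reduces to the
    crude :func:`ucl95` when E = D * R_nat.
    """
    E = np.asarray(E, dtype=float)
    if (E <= 0).any():
        raise ComputationError("standardized UCL undefined for E <= 0")
    return 100.0 * _ucl_prop(O, D, method, scale) * (np.asarray(D, dtype=float) / E) * R_nat


def _variant_scheme(variant: str, age_bins) -> StratumScheme:
    mode = {"raw": "none", "age": "age", "adi": "adi", "age_adi": "age_adi"}[variant]
    return StratumScheme(mode=mode, age_bins=age_bins)


def compute_measures(
    deaths: pd.DataFrame,
    donors: pd.DataFrame,
    crosswalk: pd.DataFrame,
    quintiles: pd.Series,
    year: int,
    variant: str,
    *,
    ci_method: str = "exact",
    age_bins=DEFAULT_AGE_BINS,
) -> pd.DataFrame:
    """RateEstimate rows (one per OPO x measure) for one year and variant."""
    return compute_all_measures(
        deaths, donors, crosswalk, quintiles, years=[year], variants=[variant],
        ci_method=ci_method, age_bins=age_bins,
    )


def compute_all_measures(
    deaths: pd.DataFrame,
    donors: pd.DataFrame,
    crosswalk: pd.DataFrame,
    quintiles: pd.Series,
    years,
    variants=VARIANTS,
    *,
    ci_method: str = "exact",
    age_bins=DEFAULT_AGE_BINS,
    drop_invalid: bool = False,
) -> pd.DataFrame:
    """Tidy rate table over years and adjustment variants.

    Columns: opo, year, measure, variant, D, O, E, rate, ucl95, ci_method,
    defined. OPOs with zero donor potential in a year get ``defined=False``
    and NaN rate/UCL; they are excluded from thresholds downstream.
    """
    if variant_bad := [v for v in variants if v not in VARIANTS]:
        raise ConfigurationError(f"unknown variant(s): {variant_bad}")
    calc, ev = resolve_cohort(deaths, donors, crosswalk, quintiles, drop_invalid=drop_invalid)
    rows = []
    for variant in variants:
        scheme = _variant_scheme(variant, age_bins)
        potentials, events = _stratified_counts_resolved(calc, ev, scheme)
        for year in years:
            nat = national_rates(potentials, events, year)
            pot_y = potentials[potentials["year"] == year]
            ev_y = events[events["year"] == year]
            D_tab = pot_y.pivot_table(index="opo", columns="stratum", values="D",
                                      aggfunc="sum", fill_value=0)
            O_tab = {
                c: ev_y.pivot_table(index="opo", columns="stratum", values=c,
                                    aggfunc="sum", fill_value=0)
                for c in ("donors", "organs", "kidneys")
            }
            opos = D_tab.index.union(O_tab["donors"].index)
            for opo in opos:
                D_s = D_tab.loc[opo] if opo in D_tab.index else pd.Series(dtype=float)
                D = float(D_s.sum())
                for measure in MEASURES:
                    col = _EVENT_COL[measure]
                    tab = O_tab[col]
                    O = float(tab.loc[opo].sum()) if opo in tab.index else 0.0
                    scale = _CI_SCALE[measure]
                    if D == 0:
                        rows.append(dict(opo=opo, year=int(year), measure=measure,
                                         variant=variant, D=0, O=O, E=0.0,
                                         rate=np.nan, ucl95=np.nan,
                                         ci_method=ci_method, defined=False))
                        continue
                    r_col = nat.r[col]
                    E = expected_events(D_s, r_col)
                    R = nat.R_nat[col]
                    if variant == "raw":
                        rate = 100.0 * O / D
                        ucl = float(ucl95(O, D, ci_method, scale))
                        E = D * R  # raw-variant equivalence, kept for conservation checks
                    else:
                        rate = standardized_rate(O, E, R) if (E > 0 or O == 0) else np.nan
                        if E > 0:
                            ucl = float(ucl95_standardized(O, D, E, R, ci_method, scale))
                        else:
                            ucl = np.nan
                    rows.append(dict(opo=opo, year=int(year), measure=measure,
                                     variant=variant, D=int(D), O=O, E=E,
                                     rate=rate, ucl95=ucl,
                                     ci_method=ci_method, defined=True))
    return pd.DataFrame(rows)
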