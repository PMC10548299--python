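"""Synthetic county-level cohort generator.

Emulates the statistical structure of the restricted inputs the tier analysis
consumes: a county table with populations, ADI values and county→OPO
assignments; individual death records with age, inpatient and cause flags;
and donor events with organ/kidney yields. Magnitudes follow the study
setting — ~3% of deaths CALC-eligible, ~0.2% of deaths missing the county of
residence, ~4% of deaths occurring outside the residence DSA, ~3 organs and
~1.5 kidneys transplanted per donor — while stratum-level donation
propensities are free scenario parameters.

Three named scenarios stress the analysis:

``null``
    The exact-collapse configuration: donation propensity 1 in every stratum,
    identical OPO effects, and a fixed integer organ/kidney yield per donor.
    Every stratum-specific event rate is then exactly constant, so crude and
    adjusted rates coincide to machine precision and reclassification is
    exactly zero — a consistency check of the standardization algebra, not a
    realistic cohort.
``adi_confounded``
    Donation propensity strictly decreasing across ADI quintiles, equal OPO
    quality, OPOs differing in ADI mix: apparent performance differences are
    pure confounding that ADI adjustment should remove.
``quality_varying``
    Flat propensities, genuinely different multiplicative OPO effects.

All randomness flows from a single integer seed through per-table
``numpy.random.SeedSequence`` child streams, so each table is reproducible
record-for-record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import NamedTuple
import json

import numpy as np
import pandas as pd

from .area_profiles import county_quintiles
from .errors import ConfigurationError, ValidationError

__all__ = [
    "ScenarioConfig",
    "Cohort",
    "make_scenario",
    "generate_counties",
    "make_crosswalk",
    "generate_death_records",
    "generate_donor_events",
    "generate_cohort",
    "SCENARIO_NAMES",
]

#: age bins used to *generate* deaths (includes the 76+ bin that can never be
#: CALC-eligible); weights default to an old-skewed mortality profile.
GENERATION_AGE_BINS = ((0, 15), (15, 25), (25, 40), (40, 55), (55, 65), (65, 76), (76, 101))
DEFAULT_AGE_WEIGHTS = (0.010, 0.015, 0.040, 0.080, 0.145, 0.250, 0.460)

#: age bins used to *stratify* the CALC-eligible population (0–75 inclusive).
STRATUM_AGE_BINS = ((0, 15), (15, 25), (25, 40), (40, 55), (55, 65), (65, 76))

SCENARIO_NAMES = ("null", "adi_confounded", "quality_varying")

# sub-stream ids, one per generated table
_STREAM_COUNTIES, _STREAM_DEATHS, _STREAM_DONORS, _STREAM_SCENARIO = 0, 1, 2, 3


def _stratum_grid(value, n_bins: int, name: str) -> np.ndarray:
    """Broadcast a scalar / per-quintile sequence / full grid to (n_bins, 5)."""
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        grid = np.full((n_bins, 5), float(arr))
    elif arr.ndim == 1 and arr.shape == (5,):
        grid = np.tile(arr, (n_bins, 1))
    elif arr.shape == (n_bins, 5):
        grid = arr.copy()
    else:
        raise ConfigurationError(
            f"{name} must be a scalar, a length-5 per-quintile sequence, "
            f"or a ({n_bins}, 5) age-bin x quintile grid"
        )
    if ((grid < 0) | (grid > 1)).any():
        raise ConfigurationError(f"{name} entries must lie in [0, 1]")
    return grid


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic cohort.

    ``years`` is an inclusive span whose first year is the burn-in year used
    only to seed prior-year tier thresholds; evaluation years are the rest.
    """

    n_counties: int
    n_opos: int = 58
    years: tuple[int, int] = (2017, 2020)
    mean_population: float = 40_000.0
    population_sigma: float = 0.8
    annual_death_rate: float = 0.0115
    adi_spread: float = 12.0          # within-OPO county ADI dispersion
    opo_adi_sd: float = 10.0          # between-OPO ADI center dispersion
    age_bin_death_rates: tuple = DEFAULT_AGE_WEIGHTS
    calc_fraction: object = 0.062     # P(CALC-eligible | death, age<=75), per stratum
    donation_propensity: object = 0.15
    opo_effects: tuple | None = None  # None -> all ones
    organs_per_donor_mean: float = 3.0
    kidneys_per_donor_mean: float = 1.5
    fixed_organ_yield: bool = False   # constant integer yields (null scenario)
    p_inpatient: float = 0.55
    p_missing_residence: float = 0.002
    p_cross_dsa: float = 0.04
    seed: int = 0

    def __post_init__(self):
        if self.n_counties <= 0 or self.n_opos <= 0:
            raise ConfigurationError("n_counties and n_opos must be positive")
        first, last = self.years
        if last - first < 1:
            raise ConfigurationError(
                "years must span at least 2 calendar years (one burn-in year "
                "is required before the first evaluation year)"
            )
        for p, name in ((self.p_inpatient, "p_inpatient"),
                        (self.p_missing_residence, "p_missing_residence"),
                        (self.p_cross_dsa, "p_cross_dsa")):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.annual_death_rate <= 0 or self.mean_population <= 0:
            raise ConfigurationError("death rate and mean population must be positive")
        if self.organs_per_donor_mean < 0 or self.kidneys_per_donor_mean < 0:
            raise ConfigurationError("organ/kidney means must be nonnegative")
        if self.kidneys_per_donor_mean > self.organs_per_donor_mean and self.organs_per_donor_mean > 0:
            raise ConfigurationError("kidneys_per_donor_mean cannot exceed organs_per_donor_mean")
        w = np.asarray(self.age_bin_death_rates, dtype=float)
        if w.shape != (len(GENERATION_AGE_BINS),) or (w < 0).any() or w.sum() <= 0:
            raise ConfigurationError("age_bin_death_rates must be nonnegative weights, one per age bin")
        if self.opo_effects is not None:
            eff = np.asarray(self.opo_effects, dtype=float)
            if eff.shape != (self.n_opos,):
                raise ConfigurationError("opo_effects must have length n_opos")
            if (eff < 0).any():
                raise ConfigurationError("opo_effects must be nonnegative")
        # normalize sequence-valued fields to tuples (stable equality and
        # JSON round trips), then validate grids eagerly
        for name in ("calc_fraction", "donation_propensity"):
            v = getattr(self, name)
            if not np.isscalar(v):
                arr = np.asarray(v, dtype=float)
                setattr(self, name,
                        tuple(map(tuple, arr)) if arr.ndim == 2 else tuple(arr))
        if self.opo_effects is not None:
            self.opo_effects = tuple(float(e) for e in self.opo_effects)
        self.years = tuple(int(y) for y in self.years)
        self.age_bin_death_rates = tuple(float(x) for x in self.age_bin_death_rates)
        self.calc_grid()
        self.propensity_grid()

    # -- derived views -----------------------------------------------------
    def calc_grid(self) -> np.ndarray:
        return _stratum_grid(self.calc_fraction, len(STRATUM_AGE_BINS), "calc_fraction")

    def propensity_grid(self) -> np.ndarray:
        return _stratum_grid(self.donation_propensity, len(STRATUM_AGE_BINS), "donation_propensity")

    def effects(self) -> np.ndarray:
        if self.opo_effects is None:
            return np.ones(self.n_opos)
        return np.asarray(self.opo_effects, dtype=float)

    @property
    def burn_in_year(self) -> int:
        return self.years[0]

    @property
    def evaluation_years(self) -> list[int]:
        return list(range(self.years[0] + 1, self.years[1] + 1))

    @property
    def all_years(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    # -- flat config file round trip --------------------------------------
    def to_json(self, path) -> None:
        """Write the config as a flat JSON document (arrays for grids)."""
        d = asdict(self)
        for key in ("calc_fraction", "donation_propensity"):
            v = d[key]
            d[key] = np.asarray(v, dtype=float).tolist() if not np.isscalar(v) else v
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ScenarioConfig":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        for key in ("years", "age_bin_death_rates", "opo_effects"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


class Cohort(NamedTuple):
    counties: pd.DataFrame
    crosswalk: pd.DataFrame
    deaths: pd.DataFrame
    donors: pd.DataFrame


def _rng(config: ScenarioConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def make_scenario(name: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Named stress-test scenario configs; see module docstring."""
    if name == "null":
        cfg = ScenarioConfig(
            n_counties=116, n_opos=58, mean_population=15_000.0,
            calc_fraction=0.06, donation_propensity=1.0,
            fixed_organ_yield=True, organs_per_donor_mean=3.0,
            kidneys_per_donor_mean=1.0, seed=seed,
        )
    elif name == "adi_confounded":
        cfg = ScenarioConfig(
            n_counties=232, n_opos=58, mean_population=38_000.0,
            opo_adi_sd=14.0,
            donation_propensity=(0.24, 0.20, 0.15, 0.10, 0.06),
            seed=seed,
        )
    elif name == "quality_varying":
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_SCENARIO]))
        effects = np.exp(rng.normal(0.0, 0.25, size=58))
        effects = np.minimum(effects, 1.0 / 0.15)  # keep propensity*effect <= 1
        cfg = ScenarioConfig(
            n_counties=232, n_opos=58, mean_population=38_000.0,
            donation_propensity=0.15, opo_effects=tuple(effects), seed=seed,
        )
    else:
        raise ConfigurationError(
            f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}"
        )
    return replace(cfg, **overrides) if overrides else cfg


def generate_counties(config: ScenarioConfig) -> pd.DataFrame:
    """Counties with population, ADI, and a static OPO assignment.

    Counties are dealt to OPOs evenly in a seeded random order (sizes differ
    by at most one county), so every OPO serves a workable population and has
    at least one county. ADI is an OPO-level center plus county-level noise,
    clipped to [1, 100], so OPOs differ in deprivation mix when
    ``opo_adi_sd`` > 0.
    """
    if config.n_counties < config.n_opos:
        raise ConfigurationError("n_counties must be at least n_opos")
    rng = _rng(config, _STREAM_COUNTIES)
    n, k = config.n_counties, config.n_opos
    opo_idx = rng.permutation(np.arange(n) % k)
    centers = rng.normal(50.0, config.opo_adi_sd, size=k)
    adi = np.clip(centers[opo_idx] + rng.normal(0.0, config.adi_spread, size=n), 1.0, 100.0)
    mu = np.log(config.mean_population) - 0.5 * config.population_sigma**2
    population = np.maximum(
        np.round(rng.lognormal(mu, config.population_sigma, size=n)), 500
    ).astype(np.int64)
    width = len(str(n))
    return pd.DataFrame(
        {
            "county_id": [f"c{i:0{width}d}" for i in range(n)],
            "population": population,
            "adi": adi,
            "opo": [f"OPO{j + 1:02d}" for j in opo_idx],
        }
    )


def make_crosswalk(counties: pd.DataFrame, years) -> pd.DataFrame:
    """Expand static county OPO assignments into a (county_id, year, opo) table."""
    frames = [
        pd.DataFrame({"county_id": counties["county_id"], "year": int(y), "opo": counties["opo"]})
        for y in years
    ]
    return pd.concat(frames, ignore_index=True)


def _sample_ages(rng: np.random.Generator, n: int, weights: np.ndarray) -> np.ndarray:
    bins = np.asarray(GENERATION_AGE_BINS)
    bin_idx = rng.choice(len(bins), size=n, p=weights / weights.sum())
    lo, hi = bins[bin_idx, 0], bins[bin_idx, 1]
    return lo + np.floor(rng.random(n) * (hi - lo)).astype(np.int64)


def _stratum_bin(age: np.ndarray) -> np.ndarray:
    """Index of the CALC stratum age bin (valid only for age <= 75)."""
    edges = np.asarray([b[0] for b in STRATUM_AGE_BINS[1:]])
    return np.digitize(age, edges)


def generate_death_records(counties: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Individual death records for every year in ``config.all_years``.

    Counts per county-year are Poisson with mean population x annual death
    rate. CALC eligibility is drawn per record from ``calc_fraction`` (by age
    bin and death-county ADI quintile) for ages <= 75 and then materialized as
    the inpatient/cause flag pair the downstream filter reads; ineligible
    records never carry both flags together with age <= 75.
    """
    if len(counties) == 0:
        raise ValidationError("county table is empty")
    rng = _rng(config, _STREAM_DEATHS)
    quint = county_quintiles(counties.set_index("county_id")["adi"])
    county_ids = counties["county_id"].to_numpy()
    county_q = quint.loc[county_ids].to_numpy()
    county_opo = counties["opo"].to_numpy()
    opo_of_county = dict(zip(county_ids, county_opo))
    weights = np.asarray(config.age_bin_death_rates, dtype=float)
    calc_grid = config.calc_grid()

    frames = []
    for year in config.all_years:
        lam = counties["population"].to_numpy() * config.annual_death_rate
        n_per_county = rng.poisson(lam)
        n = int(n_per_county.sum())
        cidx = np.repeat(np.arange(len(counties)), n_per_county)
        age = _sample_ages(rng, n, weights)
        q = county_q[cidx]

        young = age <= 75
        sbin = np.zeros(n, dtype=np.int64)
        sbin[young] = _stratum_bin(age[young])
        p_elig = np.where(young, calc_grid[sbin, q - 1], 0.0)
        eligible = rng.random(n) < p_elig

        # flags: eligible records carry both; ineligible young records never both
        inpatient = rng.random(n) < config.p_inpatient
        calc_cause = rng.random(n) < 0.05
        calc_cause[young & inpatient] = False
        inpatient[eligible] = True
        calc_cause[eligible] = True

        # residence: same county unless cross-DSA; then a county of another OPO
        res_idx = cidx.copy()
        cross = rng.random(n) < config.p_cross_dsa
        if cross.any() and config.n_opos > 1:
            pick = rng.integers(0, len(counties), size=int(cross.sum()))
            same = county_opo[pick] == county_opo[cidx[cross]]
            while same.any():
                pick[same] = rng.integers(0, len(counties), size=int(same.sum()))
                same = county_opo[pick] == county_opo[cidx[cross]]
            res_idx[cross] = pick
        residence = county_ids[res_idx].astype(object)
        missing = rng.random(n) < config.p_missing_residence
        residence[missing] = None

        frames.append(
            pd.DataFrame(
                {
                    "record_id": year * 10_000_000 + np.arange(n, dtype=np.int64),
                    "year": np.int64(year),
                    "age": age,
                    "inpatient": inpatient,
                    "calc_cause": calc_cause,
                    "county_of_death": county_ids[cidx],
                    "county_of_residence": residence,
                }
            )
        )
    deaths = pd.concat(frames, ignore_index=True)
    deaths.attrs["opo_of_county"] = opo_of_county
    return deaths


def generate_donor_events(
    deaths: pd.DataFrame, counties: pd.DataFrame, config: ScenarioConfig
) -> pd.DataFrame:
    """Donor events drawn from the CALC-eligible deaths.

    A CALC death becomes a donor with probability
    ``donation_propensity(age bin, ADI quintile) * opo_effect`` where the
    quintile is residence-based with death-county fallback (matching how the
    analysis attributes strata) and the effect belongs to the OPO of the death
    county. Organ/kidney yields are 1+Poisson / Binomial draws with the
    configured means, or fixed integers under ``fixed_organ_yield``.
    """
    rng = _rng(config, _STREAM_DONORS)
    quint = county_quintiles(counties.set_index("county_id")["adi"])
    opo_codes = sorted(counties["opo"].unique())
    opo_index = {code: i for i, code in enumerate(opo_codes)}
    effects = config.effects()

    elig = deaths[deaths["inpatient"] & deaths["calc_cause"] & (deaths["age"] <= 75)]
    if len(elig) == 0:
        return _empty_donors()

    res = elig["county_of_residence"]
    q_source = res.where(res.notna(), elig["county_of_death"])
    q = quint.loc[q_source.to_numpy()].to_numpy()
    sbin = _stratum_bin(elig["age"].to_numpy())
    opo = elig["county_of_death"].map(
        counties.set_index("county_id")["opo"]
    ).to_numpy()
    eff = effects[np.fromiter((opo_index[o] for o in opo), dtype=np.int64, count=len(opo))]
    p = config.propensity_grid()[sbin, q - 1] * eff
    if (p > 1.0 + 1e-12).any():
        raise ConfigurationError("donation propensity x opo effect exceeds 1")
    is_donor = rng.random(len(elig)) < p
    donors = elig.loc[is_donor]
    n = len(donors)
    if n == 0:
        return _empty_donors()

    om, km = config.organs_per_donor_mean, config.kidneys_per_donor_mean
    if config.fixed_organ_yield:
        organs = np.full(n, int(round(om)), dtype=np.int64)
        kidneys = np.full(n, int(round(km)), dtype=np.int64)
    else:
        if om >= 1.0:
            organs = 1 + rng.poisson(om - 1.0, size=n)
        else:
            organs = rng.poisson(om, size=n)
        ratio = 0.0 if om == 0 else min(1.0, km / om)
        kidneys = rng.binomial(organs, ratio)
    return pd.DataFrame(
        {
            "donor_id": donors["record_id"].to_numpy(),
            "year": donors["year"].to_numpy(),
            "age": donors["age"].to_numpy(),
            "hospital_county": donors["county_of_death"].to_numpy(),
            "residence_county": donors["county_of_residence"].to_numpy(),
            "organs_transplanted": organs,
            "kidneys_transplanted": kidneys,
        }
    )


def _empty_donors() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "donor_id": pd.Series(dtype=np.int64),
            "year": pd.Series(dtype=np.int64),
            "age": pd.Series(dtype=np.int64),
            "hospital_county": pd.Series(dtype=object),
            "residence_county": pd.Series(dtype=object),
            "organs_transplanted": pd.Series(dtype=np.int64),
            "kidneys_transplanted": pd.Series(dtype=np.int64),
        }
    )


def generate_cohort(config: ScenarioConfig) -> Cohort:
    """Counties, crosswalk, deaths and donors for one scenario config."""
    counties = generate_counties(config)
    crosswalk = make_crosswalk(counties, config.all_years)
    deaths = generate_death_records(counties, config)
    donors = generate_donor_events(deaths, counties, config)
    return Cohort(counties, crosswalk, deaths, donors)
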