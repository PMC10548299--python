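"""End-to-end orchestration: cohort -> profiles -> rates -> tiers -> reclassification.

A :class:`RunConfig` either names a synthetic scenario or points at input
tables on disk. :func:`run_pipeline` executes every stage, writes the output
CSVs with deterministic row/column order, and records a JSON manifest
(configuration, seed, package version, row counts) sufficient to reproduce
every output byte.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .area_profiles import build_profiles, county_quintiles, profile_correlations
from .errors import ConfigurationError, OpoMetricsError
from .performance_metrics import VARIANTS, compute_all_measures
from .reclassification import cumulative_change, rank_reassignment, summarize_reclassification
from .registry_io import (
    read_counties, read_crosswalk, read_deaths, read_donors,
    write_counties, write_crosswalk, write_deaths, write_donors, write_report,
)
from .synthetic_cohort import ScenarioConfig, generate_cohort, make_scenario
from .tiering import DEFAULT_PERCENTILE_RULE, TIER_VARIANTS, assign_all_tiers

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("opometrics")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str
    scenario: str | None = None           # named synthetic scenario, or
    scenario_config: ScenarioConfig | None = None
    counties_path: str | None = None      # ... input tables on disk
    crosswalk_path: str | None = None
    deaths_path: str | None = None
    donors_path: str | None = None
    years: tuple[int, int] | None = None  # inclusive; first year is burn-in
    variants: tuple = TIER_VARIANTS
    ci_method: str = "exact"
    threshold_rule: str = DEFAULT_PERCENTILE_RULE
    hiop_code: str | None = None
    seed: int = 0
    drop_invalid: bool = False
    write_cohort: bool = True
    quiet: bool = False


def _load_inputs(cfg: RunConfig):
    if cfg.scenario_config is not None or cfg.scenario is not None:
        sc = cfg.scenario_config or make_scenario(cfg.scenario, seed=cfg.seed)
        if cfg.years is not None:
            from dataclasses import replace
            sc = replace(sc, years=tuple(cfg.years))
        cohort = generate_cohort(sc)
        return cohort.counties, cohort.crosswalk, cohort.deaths, cohort.donors, sc
    for name in ("counties_path", "crosswalk_path", "deaths_path", "donors_path"):
        if getattr(cfg, name) is None:
            raise ConfigurationError(f"run config needs a scenario or all input paths ({name} missing)")
    counties = read_counties(cfg.counties_path)
    crosswalk = read_crosswalk(cfg.crosswalk_path)
    deaths = read_deaths(cfg.deaths_path)
    donors = read_donors(cfg.donors_path)
    if "opo" not in counties.columns:
        xw = crosswalk.sort_values("year").drop_duplicates("county_id", keep="last")
        counties = counties.merge(xw[["county_id", "opo"]], on="county_id", how="left")
    return counties, crosswalk, deaths, donors, None


def _eval_years(cfg: RunConfig, crosswalk: pd.DataFrame, sc) -> list[int]:
    if sc is not None:
        return sc.evaluation_years
    years = sorted(crosswalk["year"].unique()) if cfg.years is None else list(
        range(cfg.years[0], cfg.years[1] + 1))
    if len(years) < 2:
        raise ConfigurationError(
            "need at least 2 years of data (a burn-in year must precede the "
            "first evaluation year)"
        )
    return [int(y) for y in years[1:]]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns a dict of output paths and DataFrames."""
    if not cfg.quiet:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                            format="%(name)s %(levelname)s %(message)s")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "ingest"
    try:
        counties, crosswalk, deaths, donors, sc = _load_inputs(cfg)
        eval_years = _eval_years(cfg, crosswalk, sc)
        all_years = [eval_years[0] - 1, *eval_years]
        log.info("ingest: %d counties, %d deaths, %d donors; evaluation years %s",
                 len(counties), len(deaths), len(donors), eval_years)

        stage = "profiles"
        quintiles = county_quintiles(counties.set_index("county_id")["adi"])
        measure_cols = [c for c in counties.columns
                        if c not in ("county_id", "population", "opo")]
        profiles = build_profiles(counties, measures=measure_cols)
        correlations = profile_correlations(profiles, measure_cols)

        stage = "rates"
        rates = compute_all_measures(
            deaths, donors, crosswalk, quintiles, years=all_years,
            variants=VARIANTS, ci_method=cfg.ci_method, drop_invalid=cfg.drop_invalid,
        )
        n_undef = int((~rates["defined"]).sum())
        if n_undef:
            log.warning("rates: %d OPO-year-measure rows undefined (zero potential)", n_undef)

        stage = "tiers"
        tiers, thresholds = assign_all_tiers(
            rates, eval_years, tier_variants=cfg.variants,
            hiop_code=cfg.hiop_code, rule=cfg.threshold_rule,
        )

        stage = "reclassification"
        adj_variants = [v for v in cfg.variants if v != "calc"]
        reclass = summarize_reclassification(tiers, variants=adj_variants, years=eval_years)
        cumulative = pd.DataFrame(
            [
                {
                    "variant": v,
                    "pct_changed_at_least_once": cumulative_change(tiers, v, eval_years),
                    **{f"rank_reassigned_{m}": pct
                       for m, pct in rank_reassignment(tiers, v, eval_years).items()},
                }
                for v in adj_variants
            ]
        )
    except OpoMetricsError as exc:
        raise type(exc)(f"pipeline stage '{stage}' failed: {exc}") from exc

    stage = "write"
    paths = {}
    if cfg.write_cohort and sc is not None:
        write_counties(counties, out / "counties.csv")
        write_crosswalk(crosswalk, out / "crosswalk.csv")
        write_deaths(deaths, out / "deaths.csv")
        write_donors(donors, out / "donors.csv")
        paths.update({k: str(out / f"{k}.csv")
                      for k in ("counties", "crosswalk", "deaths", "donors")})
    write_report(profiles, out / "profiles.csv")
    write_report(correlations, out / "correlations.csv", sort_columns=["measure"])
    write_report(rates, out / "rates.csv", display_columns=("rate", "ucl95"))
    write_report(thresholds, out / "thresholds.csv",
                 sort_columns=["source_year", "measure", "variant"])
    write_report(tiers, out / "tiers.csv")
    write_report(reclass, out / "reclassification.csv",
                 display_columns=("pct_changed",), sort_columns=["variant", "year"])
    write_report(cumulative, out / "reclassification_cumulative.csv",
                 display_columns=("pct_changed_at_least_once",), sort_columns=["variant"])
    paths.update({k: str(out / f"{k}.csv")
                  for k in ("profiles", "correlations", "rates", "thresholds",
                            "tiers", "reclassification", "reclassification_cumulative")})

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": {k: v for k, v in asdict(cfg).items() if k != "scenario_config"},
        "scenario_config": None if sc is None else json.loads(
            json.dumps(asdict(sc), default=lambda o: list(o) if hasattr(o, "__iter__") else o)
        ),
        "evaluation_years": eval_years,
        "row_counts": {
            "counties": len(counties), "deaths": len(deaths), "donors": len(donors),
            "rates": len(rates), "tiers": len(tiers), "reclassification": len(reclass),
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    paths["manifest"] = str(out / "manifest.json")

    return {
        "paths": paths, "profiles": profiles, "correlations": correlations,
        "rates": rates, "thresholds": thresholds, "tiers": tiers,
        "reclassification": reclass, "cumulative": cumulative, "manifest": manifest,
    }
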