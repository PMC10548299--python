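"""Reading, validating and writing the pipeline's tabular inputs and outputs.

All tables are comma-delimited UTF-8 with a header row and ``""`` for missing
values:

========================  =====================================================
counties.csv              county_id, population, adi [, measure columns...]
crosswalk.csv             county_id, year, opo
deaths.csv                record_id, year, age, inpatient, calc_cause,
                          county_of_death, county_of_residence
donors.csv                donor_id, year, age, hospital_county,
                          residence_county, organs_transplanted,
                          kidneys_transplanted
========================  =====================================================

Validation is total: a malformed table raises :class:`SchemaError` or
:class:`ValidationError` naming the offending column/keys; records whose
assignment county cannot be resolved raise :class:`ResolutionError` unless
``drop_invalid`` is requested, in which case they are dropped and counted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ResolutionError, SchemaError, ValidationError

__all__ = [
    "read_counties", "write_counties",
    "read_crosswalk", "write_crosswalk",
    "read_deaths", "write_deaths",
    "read_donors", "write_donors",
    "crosswalk_map", "assign_opo", "assign_opo_frame",
    "assign_record_adi", "resolve_adi_quintile",
    "write_report",
]

COUNTY_COLUMNS = ("county_id", "population", "adi")
CROSSWALK_COLUMNS = ("county_id", "year", "opo")
DEATH_COLUMNS = ("record_id", "year", "age", "inpatient", "calc_cause",
                 "county_of_death", "county_of_residence")
DONOR_COLUMNS = ("donor_id", "year", "age", "hospital_county", "residence_county",
                 "organs_transplanted", "kidneys_transplanted")


def _require_columns(df: pd.DataFrame, required, table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} is missing required column(s): {', '.join(missing)}")


def read_counties(path) -> pd.DataFrame:
    """Load and validate counties.csv (unique ids, population >= 0, finite ADI)."""
    df = pd.read_csv(path, dtype={"county_id": str})
    _require_columns(df, COUNTY_COLUMNS, "counties table")
    dup = df.loc[df["county_id"].duplicated(), "county_id"].tolist()
    if dup:
        raise ValidationError(f"duplicate county_id value(s): {sorted(set(dup))}")
    if (df["population"] < 0).any():
        raise ValidationError("negative population values in counties table")
    if not np.isfinite(df["adi"].to_numpy(dtype=float)).all():
        raise ValidationError("non-finite ADI values in counties table")
    return df


def write_counties(df: pd.DataFrame, path) -> None:
    _require_columns(df, COUNTY_COLUMNS, "counties table")
    df.to_csv(path, index=False)


def read_crosswalk(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"county_id": str, "opo": str})
    _require_columns(df, CROSSWALK_COLUMNS, "crosswalk table")
    dup = df.duplicated(subset=["county_id", "year"])
    if dup.any():
        bad = df.loc[dup, ["county_id", "year"]].to_records(index=False).tolist()
        raise ValidationError(f"duplicate (county_id, year) crosswalk rows: {bad[:10]}")
    return df


def write_crosswalk(df: pd.DataFrame, path) -> None:
    _require_columns(df, CROSSWALK_COLUMNS, "crosswalk table")
    df.to_csv(path, index=False)


def read_deaths(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"county_of_death": str, "county_of_residence": str})
    _require_columns(df, DEATH_COLUMNS, "deaths table")
    if (df["age"] < 0).any():
        raise ValidationError("negative ages in deaths table")
    for col in ("inpatient", "calc_cause"):
        df[col] = df[col].astype(bool)
    df["county_of_residence"] = df["county_of_residence"].where(
        df["county_of_residence"].notna() & (df["county_of_residence"] != ""), None
    )
    return df


def write_deaths(df: pd.DataFrame, path) -> None:
    _require_columns(df, DEATH_COLUMNS, "deaths table")
    df.to_csv(path, index=False)


def read_donors(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"hospital_county": str, "residence_county": str})
    _require_columns(df, DONOR_COLUMNS, "donors table")
    if (df["organs_transplanted"] < 0).any() or (df["kidneys_transplanted"] < 0).any():
        raise ValidationError("negative organ/kidney counts in donors table")
    if (df["kidneys_transplanted"] > df["organs_transplanted"]).any():
        raise ValidationError("kidneys_transplanted exceeds organs_transplanted")
    df["residence_county"] = df["residence_county"].where(
        df["residence_county"].notna() & (df["residence_county"] != ""), None
    )
    return df


def write_donors(df: pd.DataFrame, path) -> None:
    _require_columns(df, DONOR_COLUMNS, "donors table")
    df.to_csv(path, index=False)


def crosswalk_map(crosswalk: pd.DataFrame) -> pd.Series:
    """Crosswalk as a Series indexed by (county_id, year) -> OPO code."""
    return crosswalk.set_index(["county_id", "year"])["opo"]


def assign_opo(county_id: str, crosswalk: pd.DataFrame | pd.Series, year: int) -> str:
    """OPO serving ``county_id`` in ``year`` (deaths use the death county,
    donors the hospital county)."""
    cmap = crosswalk if isinstance(crosswalk, pd.Series) else crosswalk_map(crosswalk)
    try:
        return cmap.loc[(county_id, int(year))]
    except KeyError:
        raise ResolutionError(
            f"county {county_id!r} has no OPO assignment for year {year}",
            county_id=county_id,
        ) from None


def assign_opo_frame(
    df: pd.DataFrame, crosswalk: pd.DataFrame, county_col: str, *, drop_invalid: bool = False
) -> tuple[pd.Series, int]:
    """Vectorized OPO assignment by (county, year).

    Returns (opo Series aligned to ``df``, number of dropped records). With
    ``drop_invalid=False`` any unresolvable record raises ResolutionError.
    """
    cmap = crosswalk_map(crosswalk)
    idx = pd.MultiIndex.from_arrays([df[county_col], df["year"]])
    opo = pd.Series(
        cmap.reindex(idx).to_numpy(), index=df.index, name="opo"
    )
    bad = opo.isna()
    if bad.any() and not drop_invalid:
        offender = df.loc[bad, county_col].iloc[0]
        raise ResolutionError(
            f"{int(bad.sum())} record(s) reference counties without an OPO "
            f"assignment (first offender: {offender!r})",
            county_id=offender,
        )
    return opo, int(bad.sum())


def resolve_adi_quintile(
    df: pd.DataFrame, quintiles: pd.Series, primary_col: str, fallback_col: str
) -> pd.Series:
    """ADI quintile of the residence county, falling back to the death (or
    hospital) county when residence is missing."""
    primary = df[primary_col]
    source = primary.where(primary.notna(), df[fallback_col])
    q = source.map(quintiles)
    if q.isna().any():
        offender = source[q.isna()].iloc[0]
        raise ResolutionError(
            f"county {offender!r} has no ADI quintile", county_id=offender
        )
    return q.astype(np.int64)


def assign_record_adi(record: pd.Series | dict, quintiles: pd.Series) -> int:
    """Single-record convenience wrapper around :func:`resolve_adi_quintile`."""
    rec = dict(record)
    primary = rec.get("county_of_residence", rec.get("residence_county"))
    fallback = rec.get("county_of_death", rec.get("hospital_county"))
    for county in (primary, fallback):
        if county is not None and not (isinstance(county, float) and np.isnan(county)):
            if county in quintiles.index:
                return int(quintiles.loc[county])
            raise ResolutionError(f"county {county!r} has no ADI quintile", county_id=county)
    raise ResolutionError("record has neither residence nor death county", county_id=None)


def write_report(df: pd.DataFrame, path, *, display_columns=(), sort_columns=None) -> None:
    """Write an output table deterministically.

    Rows are sorted by ``sort_columns`` (default: whichever of opo, year,
    tier_variant, variant, measure are present), numeric values are kept at
    full ``repr`` precision, and each column named in ``display_columns``
    gains a ``<col>_display`` companion rounded for presentation (1 decimal,
    2 decimals below 1).
    """
    out = df.copy()
    if sort_columns is None:
        sort_columns = [c for c in ("opo", "year", "tier_variant", "variant", "measure")
                        if c in out.columns]
    if sort_columns:
        out = out.sort_values(sort_columns, kind="stable").reset_index(drop=True)
    for col in display_columns:
        out[f"{col}_display"] = [display_round(v) for v in out[col]]
    out.to_csv(path, index=False)


def display_round(value: float) -> float:
    """Presentation rounding: 1 decimal place, 2 decimals for values below 1."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return float("nan")
    return round(float(value), 2 if abs(value) < 1.0 else 1)
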