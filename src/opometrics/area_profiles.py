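"""County ADI quintiles, population-weighted OPO profiles, and OPO-level
rank correlations.

Two distinct rankings are implemented: national county quintiles (every county
ranked by its ADI value) and OPO quintiles (the 58 OPOs ranked by their
population-weighted median ADI). Both use the same quintile rule:
``quintile = ceil(5 * rank / n)`` on ordinal ranks, with tied values forced
into the lowest quintile any of them would occupy, which keeps the assignment
monotone in ADI and permutation-invariant.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, SchemaError

__all__ = [
    "county_quintiles",
    "weighted_median",
    "spearman_rho",
    "spearman_exact_p",
    "build_profiles",
    "opo_quintiles",
    "profile_correlations",
]


def _quintile_rule(values: np.ndarray) -> np.ndarray:
    """ceil(5*rank/n) on ordinal ranks; ties share the lowest applicable quintile."""
    n = len(values)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(1, n + 1)
    q = np.ceil(5.0 * ranks / n).astype(np.int64)
    # force equal values into one (lowest) quintile
    df = pd.DataFrame({"v": values, "q": q})
    q = df.groupby("v")["q"].transform("min").to_numpy()
    return q


def county_quintiles(adi) -> pd.Series:
    """National ADI quintile (1 = least deprived, 5 = most) for each county.

    Parameters
    ----------
    adi : pandas.Series
        ADI value per county, indexed by county id. Requires at least five
        counties with finite values.

    Returns
    -------
    pandas.Series of int in {1..5} with the same index.
    """
    adi = pd.Series(adi, dtype=float)
    if len(adi) < 5:
        raise ComputationError("quintile ranking needs at least 5 counties")
    if not np.isfinite(adi.to_numpy()).all():
        raise ComputationError("non-finite ADI values in quintile ranking")
    return pd.Series(_quintile_rule(adi.to_numpy()), index=adi.index, name="adi_quintile")


def weighted_median(values, weights) -> float:
    """Lower weighted median: smallest v with cumulative weight(x <= v) >= W/2.

    Weights must be nonnegative with a positive sum; with equal weights this
    equals the ordinary lower median.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape or v.ndim != 1:
        raise ComputationError("values and weights must be 1-D and equally long")
    if not np.isfinite(v).all():
        raise ComputationError("non-finite values in weighted_median")
    if (w < 0).any():
        raise ComputationError("negative weights in weighted_median")
    total = w.sum()
    if total <= 0:
        raise ComputationError("weights sum to zero in weighted_median")
    order = np.argsort(v, kind="stable")
    cw = np.cumsum(w[order])
    idx = int(np.searchsorted(cw, 0.5 * total, side="left"))
    return float(v[order][idx])


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties.

    Returns ``(rho, p)`` where p is the two-sided large-sample
    t-approximation. Constant input vectors raise ComputationError (the
    correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ComputationError("spearman_rho needs equal-length 1-D vectors, n >= 3")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ComputationError("spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def spearman_exact_p(x, y) -> float:
    """Exact two-sided permutation p-value for Spearman's rho, n <= 10.

    Enumerates all n! pairings of the rank vectors; p is the fraction of
    permutations with |rho| >= |observed rho| (within 1e-12). Intended as a
    small-sample oracle; cost grows factorially.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n > 10:
        raise ComputationError("exact permutation p limited to n <= 10")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(_rho_of_ranks(rx, ry))
    hits = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if abs(_rho_of_ranks(rx, ry[list(perm)])) >= obs - 1e-12:
            hits += 1
    return hits / total


def build_profiles(counties: pd.DataFrame, measures=("adi",), opo_col: str = "opo") -> pd.DataFrame:
    """Population-weighted median of each measure per OPO.

    ``counties`` must carry ``population``, the requested measure columns, and
    an OPO assignment column. Returns one row per OPO with
    ``weighted_median_<measure>`` columns, total population, county count and
    the OPO-level ADI quintile (OPOs ranked by weighted-median ADI).
    """
    for col in (*measures, "population", opo_col):
        if col not in counties.columns:
            raise SchemaError(f"counties table lacks required column '{col}'")
    rows = []
    for opo, grp in counties.groupby(opo_col, sort=True):
        row = {"opo": opo, "population": int(grp["population"].sum()),
               "n_counties": len(grp)}
        for m in measures:
            row[f"weighted_median_{m}"] = weighted_median(
                grp[m].to_numpy(), grp["population"].to_numpy()
            )
        rows.append(row)
    profiles = pd.DataFrame(rows)
    if "adi" in measures and len(profiles) >= 5:
        profiles["adi_quintile_of_opo"] = opo_quintiles(
            profiles.set_index("opo")["weighted_median_adi"]
        ).to_numpy()
    return profiles


def opo_quintiles(weighted_median_adi: pd.Series) -> pd.Series:
    """Quintile of each OPO when all OPOs are ranked by weighted-median ADI."""
    if len(weighted_median_adi) < 5:
        raise ComputationError("OPO quintiles need at least 5 OPOs")
    return pd.Series(
        _quintile_rule(np.asarray(weighted_median_adi, dtype=float)),
        index=weighted_median_adi.index,
        name="adi_quintile_of_opo",
    )


def profile_correlations(profiles: pd.DataFrame, measures) -> pd.DataFrame:
    """Spearman correlation of every measure against weighted-median ADI."""
    out = []
    adi = profiles["weighted_median_adi"].to_numpy()
    for m in measures:
        if m == "adi":
            continue
        col = f"weighted_median_{m}" if f"weighted_median_{m}" in profiles else m
        if col not in profiles:
            raise SchemaError(f"profiles table lacks measure column '{col}'")
        rho, p = spearman_rho(adi, profiles[col].to_numpy())
        out.append({"measure": m, "rho": rho, "p_value": p, "n": len(profiles)})
    return pd.DataFrame(out, columns=["measure", "rho", "p_value", "n"])
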