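"""Point extraction of bioclimatic values and species-level summaries.

Each cleaned presence point is assigned the value of every layer at the
grid cell containing it (half-open cell intervals, north-up grid).  The
water supply/demand ratio AET/PET is computed per point from the AET
and PET layers, since the layers are co-registered; cells with PET = 0
are treated as nodata for the ratio.  Per species, the mean of each
indicator is the univariate *habitat position* and max - min its
*habitat range*; species with fewer than three usable points are
excluded, mirroring the minimum-sample rule of the cleaning stage.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grids import INDICATORS, ClimateStack

logger = logging.getLogger(__name__)


def extract_values(stack: ClimateStack, records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample all indicator values at each record's grid cell.

    Returns ``(values, dropped)``.  ``values`` has one row per usable
    record with columns ``species, record_id, longitude, latitude`` and
    one column per indicator (MAP, AI, AET_PET, P_dry, P_seas).
    Records outside the grid, or on nodata in any required layer, are
    dropped and returned with a reason.
    """
    geom = stack.geometry
    lon = records["longitude"].to_numpy(float)
    lat = records["latitude"].to_numpy(float)
    row, col = geom.cell_index(lon, lat)
    inside = geom.contains(row, col)

    n = len(records)
    out = records[["species", "record_id", "longitude", "latitude"]].copy()
    reason = np.where(inside, "", "outside grid")
    r_in, c_in = np.clip(row, 0, geom.n_rows - 1), np.clip(col, 0, geom.n_cols - 1)

    cols: dict[str, np.ndarray] = {}
    for name in ("MAP", "AI", "P_dry", "P_seas"):
        vals = stack[name][r_in, c_in].astype(float)
        nodata_hit = inside & (vals == stack.nodata[name])
        reason = np.where((reason == "") & nodata_hit, f"nodata in {name}", reason)
        cols[name] = vals
    aet = stack["AET"][r_in, c_in].astype(float)
    pet = stack["PET"][r_in, c_in].astype(float)
    bad_ratio = inside & (
        (aet == stack.nodata["AET"]) | (pet == stack.nodata["PET"]) | (pet == 0)
    )
    reason = np.where((reason == "") & bad_ratio, "nodata in AET/PET", reason)
    with np.errstate(divide="ignore", invalid="ignore"):
        cols["AET_PET"] = aet / pet

    for name in INDICATORS:
        out[name] = cols[name]
    ok = reason == ""
    values = out[ok].reset_index(drop=True)
    dropped = out[~ok].assign(reason=reason[~ok]).reset_index(drop=True)
    if len(dropped):
        logger.info("extract_values: dropped %d of %d points", len(dropped), n)
    return values, dropped


def summarize_species(
    values: pd.DataFrame, min_points: int = 3
) -> tuple[pd.DataFrame, list[str]]:
    """Reduce per-point values to species habitat position and range.

    Returns ``(summaries, excluded_species)``.  For every indicator the
    summary holds ``<var>_mean`` (habitat position), ``<var>_min``,
    ``<var>_max`` and ``<var>_range`` = max - min (habitat range), plus
    ``n_points_used``.  Species with fewer than ``min_points`` usable
    points are excluded and listed.
    """
    if values.empty:
        return (
            pd.DataFrame(columns=["species", "n_points_used"]),
            [],
        )
    g = values.groupby("species", sort=True)
    summary = pd.DataFrame({"n_points_used": g.size()})
    for var in INDICATORS:
        agg = g[var].agg(["mean", "min", "max"])
        summary[f"{var}_mean"] = agg["mean"]
        summary[f"{var}_min"] = agg["min"]
        summary[f"{var}_max"] = agg["max"]
        summary[f"{var}_range"] = agg["max"] - agg["min"]
    excluded = summary.index[summary["n_points_used"] < min_points].tolist()
    if excluded:
        logger.info("summarize_species: excluded %d species with <%d points", len(excluded), min_points)
    summary = summary.drop(index=excluded).reset_index(names="species")
    return summary, [str(s) for s in excluded]


def variable_collinearity_screen(
    summaries: pd.DataFrame,
    variables: Sequence[str] = INDICATORS,
    threshold: float = 0.70,
) -> pd.DataFrame:
    """Pairwise linear and quadratic r-squared over species means.

    For every unordered variable pair the screen fits ordinary linear
    and quadratic least squares of one species-mean column on another
    and reports ``r2 = max(r2_linear, r2_quadratic)``; pairs above the
    threshold are flagged as collinear.  A zero-variance variable makes
    its pairs undefined (NaN), not an error.
    """
    if len(summaries) < 3:
        raise ValueError("collinearity screen requires at least 3 species")
    rows = []
    for i, a in enumerate(variables):
        for b in variables[i + 1 :]:
            x = summaries[f"{a}_mean"].to_numpy(float)
            y = summaries[f"{b}_mean"].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r2_lin = r2_quad = np.nan
            else:
                r2_lin = stats.pearsonr(x, y).statistic ** 2
                r2_quad = _polyfit_r2(x, y, 2)
            r2 = np.nanmax([r2_lin, r2_quad]) if np.isfinite(r2_lin) else np.nan
            rows.append(
                {
                    "var_a": a,
                    "var_b": b,
                    "r2_linear": r2_lin,
                    "r2_quadratic": r2_quad,
                    "r2": r2,
                    "collinear": bool(r2 > threshold) if np.isfinite(r2) else False,
                }
            )
    return pd.DataFrame(rows)


def _polyfit_r2(x: np.ndarray, y: np.ndarray, degree: int) -> float:
    coef = np.polynomial.polynomial.polyfit(x, y, degree)
    resid = y - np.polynomial.polynomial.polyval(x, coef)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return np.nan
    return 1.0 - np.sum(resid**2) / ss_tot
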