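"""Canned synthetic study designs used for validation.

Each function builds one self-contained experiment on a synthetic
landscape: a cohort of species with known niche truth, pushed through
the relevant pipeline stages.  These designs back the package's
simulation-based checks (parameter recovery, the breadth-driven
range-size relationship and its negative control, the two-block PCA
structure, contamination cleaning), and are importable so scripts and
tests exercise exactly the same study conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cleaning import clean_occurrences
from .extraction import extract_values, summarize_species
from .georange import species_georanges
from .grids import INDICATORS, ClimateStack
from .synth import (
    ContaminationSpec,
    LandscapeSpec,
    NicheSpec,
    generate_climate_stack,
    generate_species_occurrences,
    inject_contaminants,
    native_boxes_from_occurrences,
)


def default_landscape(seed: int = 11) -> ClimateStack:
    """The standard synthetic landscape: default field recipe."""
    return generate_climate_stack(LandscapeSpec(seed=seed))


def _value_band(stack: ClimateStack, variable: str) -> tuple[float, float, float]:
    """(10th pct, 90th pct, full range) of a layer's valid cell values."""
    v = stack[variable][stack.mask(variable)].ravel()
    lo, hi = np.percentile(v, [10, 90])
    return float(lo), float(hi), float(v.max() - v.min())


def breadth_recovery_cohort(
    stack: ClimateStack,
    seed: int,
    n_species: int = 50,
    n_points: int = 100,
    variable: str = "MAP",
    breadth_span: tuple[float, float] = (0.05, 0.5),
) -> pd.DataFrame:
    """Species with breadths spanning 10x, for parameter recovery.

    Niche breadths for ``variable`` are spaced geometrically over
    ``breadth_span`` as fractions of the landscape's value range, with
    optima drawn uniformly over the central (10th-90th percentile)
    value band.  Returns species summaries merged with the truth table.
    """
    rng = np.random.default_rng(seed)
    lo, hi, full = _value_band(stack, variable)
    sigmas = np.geomspace(breadth_span[0], breadth_span[1], n_species) * full
    rng.shuffle(sigmas)
    niches = [
        NicheSpec(
            f"rec{i:03d}",
            {variable: float(rng.uniform(lo, hi))},
            {variable: float(s)},
            n_points=n_points,
        )
        for i, s in enumerate(sigmas)
    ]
    occ, truth = generate_species_occurrences(stack, niches, seed=seed)
    values, _ = extract_values(stack, occ)
    summaries, _ = summarize_species(values)
    return summaries.merge(truth, on="species")


def breadth_recovery_rho(cohort: pd.DataFrame, variable: str = "MAP") -> float:
    """Spearman rank correlation of true breadth vs. estimated range."""
    return float(
        stats.spearmanr(cohort[f"{variable}_breadth"], cohort[f"{variable}_range"]).statistic
    )


def breadth_driven_cohort(
    stack: ClimateStack, seed: int, n_species: int = 40, n_points: int = 80
) -> pd.DataFrame:
    """Cohort where niche breadth drives spatial spread.

    One shared breadth scale per species acts on both climate blocks
    (MAP and P_seas), so climatically narrow species are spatially
    confined along both landscape gradients and climatically tolerant
    ones range widely.  Returns habitat summaries merged with extent of
    occurrence (``area_km2``), ready for range-size regressions.
    """
    rng = np.random.default_rng(seed)
    m_lo, m_hi, m_full = _value_band(stack, "MAP")
    s_lo, s_hi, s_full = _value_band(stack, "P_seas")
    scales = np.geomspace(0.05, 0.5, n_species)
    rng.shuffle(scales)
    niches = [
        NicheSpec(
            f"pos{i:03d}",
            {"MAP": float(rng.uniform(m_lo, m_hi)), "P_seas": float(rng.uniform(s_lo, s_hi))},
            {"MAP": float(k * m_full), "P_seas": float(k * s_full)},
            n_points=n_points,
        )
        for i, k in enumerate(scales)
    ]
    occ, _ = generate_species_occurrences(stack, niches, seed=seed)
    values, _ = extract_values(stack, occ)
    summaries, _ = summarize_species(values)
    return summaries.merge(species_georanges(occ), on="species")


def fixed_extent_cohort(
    stack: ClimateStack,
    seed: int,
    n_species: int = 20,
    n_points: int = 40,
    box_deg: float = 1.0,
) -> pd.DataFrame:
    """Negative control: every species occupies the same spatial extent.

    Points are drawn uniformly in a ``box_deg``-sized box at a random
    landscape location per species, decoupling geographic spread from
    climatic breadth.  Returns summaries merged with EOO areas.
    """
    rng = np.random.default_rng(seed)
    geom = stack.geometry
    rows = []
    for i in range(n_species):
        lon0 = rng.uniform(geom.origin_lon + 0.5, geom.lon_max - 0.5 - box_deg)
        lat0 = rng.uniform(geom.lat_min + 0.5 + box_deg, geom.origin_lat - 0.5)
        rows.append(
            pd.DataFrame(
                {
                    "species": f"nul{i:03d}",
                    "longitude": rng.uniform(lon0, lon0 + box_deg, n_points),
                    "latitude": rng.uniform(lat0 - box_deg, lat0, n_points),
                    "record_id": [f"nul{i:03d}_{j:04d}" for j in range(n_points)],
                }
            )
        )
    occ = pd.concat(rows, ignore_index=True)
    values, _ = extract_values(stack, occ)
    summaries, _ = summarize_species(values)
    return summaries.merge(species_georanges(occ), on="species")


def range_size_regressions(merged: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Per indicator: (slope, p) of log10(area_km2 + 1) on habitat range."""
    from .assoc import linear_regression

    out = {}
    for var in INDICATORS:
        r = linear_regression(
            merged[f"{var}_range"], merged["area_km2"], log_y=True, label=var
        )
        out[var] = (r.slope, r.p_value) if r is not None else (float("nan"), float("nan"))
    return out


def two_block_summaries(seed: int, n_species: int = 500, loading: float = 0.9) -> pd.DataFrame:
    """Species summaries with an exact two-factor block structure.

    A moisture factor drives MAP, AI and AET/PET and a seasonality
    factor drives P_seas and P_dry, each with the given loading on the
    log scale the PCA operates on; the remainder is independent noise.
    Used to confirm the PCA recovers two dominant axes with
    block-aligned loadings.
    """
    rng = np.random.default_rng(seed)
    f_moist = rng.normal(size=n_species)
    f_seas = rng.normal(size=n_species)
    resid = np.sqrt(1.0 - loading**2)
    data: dict[str, np.ndarray] = {}
    blocks = {"MAP": f_moist, "AI": f_moist, "AET_PET": f_moist, "P_seas": f_seas, "P_dry": f_seas}
    for var, factor in blocks.items():
        z = loading * factor + resid * rng.normal(size=n_species)
        # Pre-invert the pipeline's log10(x + 1) transform so the block
        # structure is exact in the space the PCA sees.
        x = 10.0 ** (0.2 * z + 3.0) - 1.0
        data[f"{var}_mean"] = x
        data[f"{var}_range"] = x
    out = pd.DataFrame(data)
    out.insert(0, "species", [f"blk{i:04d}" for i in range(n_species)])
    out["n_points_used"] = 10
    return out


def contaminated_occurrence_set(
    stack: ClimateStack,
    seed: int,
    n_species: int = 12,
    n_points: int = 40,
    contamination: ContaminationSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """A labelled contaminated occurrence set with its native boxes.

    Returns ``(records, native_boxes, truth)`` where ``records`` carries
    per-record truth labels in a ``label`` column.  The default
    contamination appends, per species, two duplicates, one record at a
    herbarium coordinate and two records displaced out of range.
    """
    rng = np.random.default_rng(seed)
    lo, hi, full = _value_band(stack, "MAP")
    niches = [
        NicheSpec(
            f"cln{i:02d}",
            {"MAP": float(rng.uniform(lo, hi))},
            {"MAP": float(rng.uniform(0.05, 0.35) * full)},
            n_points=n_points,
        )
        for i in range(n_species)
    ]
    occ, truth = generate_species_occurrences(stack, niches, seed=seed)
    boxes = native_boxes_from_occurrences(occ, pad=1e-9)
    if contamination is None:
        contamination = ContaminationSpec(
            n_duplicates=2,
            institution_points=((-52.73, 5.01), (-47.87, -15.79)),
            n_institution=1,
            n_out_of_range=2,
            seed=seed,
        )
    dirty = inject_contaminants(occ, boxes, contamination)
    return dirty, boxes, truth


def cleaning_truth_agreement(dirty: pd.DataFrame, boxes: pd.DataFrame) -> tuple[bool, object]:
    """Clean a labelled set and compare with the truth labels.

    Returns ``(exact_match, report)`` where ``exact_match`` is True when
    the retained record ids equal the ids labelled clean, at zero
    institution tolerance and the generator's own native boxes.
    """
    inst = sorted(
        set(
            map(
                tuple,
                dirty.loc[dirty["label"] == "institution", ["longitude", "latitude"]].to_numpy(),
            )
        )
    )
    retained, report = clean_occurrences(
        dirty.drop(columns="label"),
        native_regions=boxes,
        institution_points=inst,
        institution_tolerance_deg=0.0,
    )
    truth_ids = set(dirty.loc[dirty["label"] == "clean", "record_id"])
    return set(retained["record_id"]) == truth_ids, report
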