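"""Seeded synthetic landscapes and niche-constrained occurrence records.

The generator emulates the statistical structure the downstream analysis
assumes: spatially autocorrelated precipitation / evapotranspiration
fields organised in two correlated blocks (overall moisture: MAP, AET,
PET and the derived AI; seasonality: P_seas, P_dry), and species whose
presence points are drawn from Gaussian suitability kernels with known
optima and breadths.  Because every species' true niche parameters are
recorded in a truth table, parameter-recovery and contamination-removal
behaviour of the pipeline can be tested without any external downloads.

All generators are pure functions of their spec including the seed:
identical inputs give bit-identical outputs, and per-species random
sub-streams are derived by stable hashing of the species name so output
does not depend on species insertion order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import ClimateStack, GridGeometry, DEFAULT_NODATA

MOISTURE_BLOCK = ("MAP", "AET", "PET")
SEASONALITY_BLOCK = ("P_seas", "P_dry")

# Within-block sign of each variable's coupling to its block latent:
# high-PET cells are the dry ones, and a strongly seasonal climate has a
# drier driest month.
_BLOCK_SIGN = {"MAP": 1.0, "AET": 1.0, "PET": -1.0, "P_seas": 1.0, "P_dry": -1.0}


@dataclass(frozen=True)
class FieldSpec:
    """One smoothed noise field: level, spread, autocorrelation, bounds."""

    base_level: float
    amplitude: float
    smoothing_length_cells: float
    clamp_min: float
    clamp_max: float

    def __post_init__(self) -> None:
        if self.clamp_min > self.clamp_max:
            raise ValueError("clamp_min must not exceed clamp_max")
        if self.clamp_min < 0:
            raise ValueError("clamp_min must be nonnegative")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.smoothing_length_cells < 0:
            raise ValueError("smoothing_length_cells must be nonnegative")


def _default_fields() -> dict[str, FieldSpec]:
    # Magnitudes bracket the humid-to-arid Neotropical gradient the
    # source layers span; PET is kept strictly positive so the aridity
    # index is defined everywhere by default.
    return {
        "MAP": FieldSpec(1500.0, 1300.0, 6.0, 0.0, 8000.0),
        "P_dry": FieldSpec(60.0, 60.0, 6.0, 0.0, 400.0),
        "P_seas": FieldSpec(60.0, 45.0, 6.0, 0.0, 150.0),
        "AET": FieldSpec(1100.0, 600.0, 6.0, 0.0, 2000.0),
        "PET": FieldSpec(1500.0, 500.0, 6.0, 200.0, 2500.0),
    }


@dataclass(frozen=True)
class LandscapeSpec:
    """Recipe for a synthetic six-layer bioclimatic stack."""

    n_cols: int = 120
    n_rows: int = 100
    origin_lon: float = -75.0
    origin_lat: float = 0.0
    cell_size: float = 0.05
    fields: dict[str, FieldSpec] = field(default_factory=_default_fields)
    cross_block_correlation: float = -0.3
    own_noise_weight: float = 0.35
    gradient_weight: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cols < 2 or self.n_rows < 2:
            raise ValueError("n_cols and n_rows must be at least 2")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not -1.0 <= self.cross_block_correlation <= 1.0:
            raise ValueError("cross_block_correlation must lie in [-1, 1]")
        if not 0.0 <= self.own_noise_weight < 1.0:
            raise ValueError("own_noise_weight must lie in [0, 1)")
        if not 0.0 <= self.gradient_weight < 1.0:
            raise ValueError("gradient_weight must lie in [0, 1)")
        missing = set(_default_fields()) - set(self.fields)
        if missing:
            raise ValueError(f"fields missing for variables: {sorted(missing)}")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(
            origin_lon=self.origin_lon,
            origin_lat=self.origin_lat,
            cell_size=self.cell_size,
            n_cols=self.n_cols,
            n_rows=self.n_rows,
        )


def _species_rng(base_seed: int, species_id: str, extra: int = 0) -> np.random.Generator:
    """Sub-stream keyed by a stable hash of the species name."""
    tag = zlib.crc32(species_id.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([base_seed & 0x7FFFFFFF, tag, extra]))


def _standardize(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, float)
    sd = arr.std()
    return (arr - arr.mean()) / sd if sd > 0 else arr - arr.mean()


def _smooth_unit_field(rng: np.random.Generator, shape: tuple[int, int], length: float) -> np.ndarray:
    """Uniform noise convolved with a Gaussian kernel, standardized."""
    raw = rng.uniform(-1.0, 1.0, size=shape)
    if length > 0:
        raw = ndimage.gaussian_filter(raw, sigma=length, mode="reflect")
    sd = raw.std()
    if sd > 0:
        raw = (raw - raw.mean()) / sd
    return raw


def generate_climate_stack(spec: LandscapeSpec) -> ClimateStack:
    """Generate the six co-registered layers from a landscape recipe.

    MAP, P_dry, P_seas, AET and PET are smoothed seeded noise fields,
    affinely rescaled to ``[base - amplitude, base + amplitude]`` and
    clamped to their bounds; AI is then derived cell-wise as
    ``round(1e4 * MAP / PET)`` (nodata where PET is zero), following the
    scaled-integer convention of the source aridity layers.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.n_rows, spec.n_cols)

    # Each block latent mixes a deterministic large-scale gradient (the
    # continental moisture / seasonality trend; gradients of the two
    # blocks run along perpendicular axes) with a smoothed noise field.
    # Block latents share one smoothing length so the cross-block mixing
    # is exact before per-variable noise is added.
    ref_length = spec.fields["MAP"].smoothing_length_cells
    g = spec.gradient_weight
    ramp_cols = _standardize(np.broadcast_to(np.linspace(-1, 1, spec.n_cols), shape))
    ramp_rows = _standardize(np.broadcast_to(np.linspace(-1, 1, spec.n_rows)[:, None], shape))
    latent_m = _standardize(
        np.sqrt(g) * ramp_cols + np.sqrt(1 - g) * _smooth_unit_field(rng, shape, ref_length)
    )
    latent_s_indep = _standardize(
        np.sqrt(g) * ramp_rows + np.sqrt(1 - g) * _smooth_unit_field(rng, shape, ref_length)
    )
    # Smoothing leaves few effective degrees of freedom, so two
    # independent fields can show sizeable chance correlation; enforce
    # the target correlation in-sample by orthogonalizing first.
    latent_s_indep = _standardize(
        latent_s_indep - latent_m * float(np.mean(latent_m * latent_s_indep))
    )
    rho = spec.cross_block_correlation
    latent_s = rho * latent_m + np.sqrt(max(0.0, 1.0 - rho**2)) * latent_s_indep

    w = spec.own_noise_weight
    layers: dict[str, np.ndarray] = {}
    for name in ("MAP", "P_dry", "P_seas", "AET", "PET"):
        fs = spec.fields[name]
        block = latent_m if name in MOISTURE_BLOCK else latent_s
        own = _smooth_unit_field(rng, shape, fs.smoothing_length_cells)
        raw = _BLOCK_SIGN[name] * np.sqrt(1.0 - w**2) * block + w * own
        lo, hi = raw.min(), raw.max()
        if hi > lo and fs.amplitude > 0:
            scaled = fs.base_level - fs.amplitude + 2.0 * fs.amplitude * (raw - lo) / (hi - lo)
        else:
            scaled = np.full(shape, fs.base_level)
        layers[name] = np.clip(scaled, fs.clamp_min, fs.clamp_max)

    pet = layers["PET"]
    ai = np.full(shape, DEFAULT_NODATA)
    ok = pet > 0
    ai[ok] = np.round(1e4 * layers["MAP"][ok] / pet[ok])
    layers["AI"] = ai

    nodata = {name: DEFAULT_NODATA for name in layers}
    return ClimateStack(geometry=spec.geometry, layers=layers, nodata=nodata)


# --------------------------------------------------------------------------
# Niche-constrained occurrence sampling


@dataclass(frozen=True)
class NicheSpec:
    """True Gaussian niche of one synthetic species.

    ``optima`` and ``breadths`` are keyed by indicator name (any of MAP,
    AI, AET_PET, P_dry, P_seas); ``breadths`` are the standard
    deviations of the suitability kernel in the variable's units.
    """

    species_id: str
    optima: Mapping[str, float]
    breadths: Mapping[str, float]
    n_points: int = 50
    coordinate_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be at least 1")
        if set(self.optima) != set(self.breadths):
            raise ValueError("optima and breadths must cover the same variables")
        for var, sigma in self.breadths.items():
            if sigma <= 0:
                raise ValueError(f"breadth for {var!r} must be positive")


def indicator_fields(stack: ClimateStack) -> dict[str, np.ndarray]:
    """Cell-wise indicator values (masked arrays with NaN at nodata)."""
    out: dict[str, np.ndarray] = {}
    for name in ("MAP", "AI", "P_dry", "P_seas"):
        arr = stack[name].astype(float).copy()
        arr[~stack.mask(name)] = np.nan
        out[name] = arr
    aet, pet = stack["AET"].astype(float), stack["PET"].astype(float)
    ratio = np.full(aet.shape, np.nan)
    ok = stack.mask("AET") & stack.mask("PET") & (pet != 0)
    ratio[ok] = aet[ok] / pet[ok]
    out["AET_PET"] = ratio
    return out


def generate_species_occurrences(
    stack: ClimateStack, niches: Sequence[NicheSpec], seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample presence points for each species from its suitability kernel.

    Cells are drawn with probability proportional to the product of
    Gaussian kernels ``exp(-(v - opt_v)^2 / (2 sigma_v^2))`` over the
    variables named in each :class:`NicheSpec`; each sampled point is
    placed uniformly within its cell, plus the spec's coordinate jitter.

    Returns ``(occurrences, truth)``: the occurrence table with columns
    ``species, longitude, latitude, record_id`` and a per-species truth
    table of the specified optima, breadths and point counts.
    """
    fields = indicator_fields(stack)
    geom = stack.geometry
    rows_out: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    dead_species: list[str] = []

    for niche in niches:
        log_w = np.zeros(fields["MAP"].shape)
        valid = np.ones(log_w.shape, dtype=bool)
        for var, opt in niche.optima.items():
            if var not in fields:
                raise ValueError(f"unknown indicator variable {var!r}")
            v = fields[var]
            valid &= np.isfinite(v)
            sigma = niche.breadths[var]
            with np.errstate(invalid="ignore"):
                log_w = log_w - (v - opt) ** 2 / (2.0 * sigma**2)
        log_w[~valid] = -np.inf
        # Mass is "numerically zero" when even the best cell's kernel
        # value underflows double precision.
        if not np.any(valid) or log_w[valid].max() < np.log(np.finfo(float).tiny):
            dead_species.append(niche.species_id)
            continue
        # Stabilize before exponentiation so narrow kernels keep mass.
        w = np.exp(log_w - log_w[valid].max())
        total = w.sum()
        if not np.isfinite(total) or total <= 0:
            dead_species.append(niche.species_id)
            continue

        rng = _species_rng(seed, niche.species_id, extra=niche.seed)
        flat_idx = rng.choice(w.size, size=niche.n_points, p=(w / total).ravel())
        row, col = np.unravel_index(flat_idx, w.shape)
        lon = geom.origin_lon + (col + rng.uniform(0.0, 1.0, niche.n_points)) * geom.cell_size
        lat = geom.origin_lat - (row + rng.uniform(0.0, 1.0, niche.n_points)) * geom.cell_size
        if niche.coordinate_jitter > 0:
            j = niche.coordinate_jitter
            lon = lon + rng.uniform(-j, j, niche.n_points)
            lat = lat + rng.uniform(-j, j, niche.n_points)
        rows_out.append(
            pd.DataFrame(
                {
                    "species": niche.species_id,
                    "longitude": lon,
                    "latitude": lat,
                    "record_id": [f"{niche.species_id}_{i:05d}" for i in range(niche.n_points)],
                }
            )
        )
        rec: dict = {"species": niche.species_id, "n_points": niche.n_points}
        for var in niche.optima:
            rec[f"{var}_optimum"] = niche.optima[var]
            rec[f"{var}_breadth"] = niche.breadths[var]
        truth_rows.append(rec)

    if dead_species:
        raise ValueError(
            "suitability kernel has zero mass over the landscape for species: "
            + ", ".join(sorted(dead_species))
        )
    occurrences = pd.concat(rows_out, ignore_index=True) if rows_out else pd.DataFrame(
        columns=["species", "longitude", "latitude", "record_id"]
    )
    truth = pd.DataFrame(truth_rows)
    return occurrences, truth


def native_boxes_from_occurrences(occurrences: pd.DataFrame, pad: float = 0.0) -> pd.DataFrame:
    """Tight per-species bounding boxes around a set of clean points."""
    g = occurrences.groupby("species")
    out = pd.DataFrame(
        {
            "lon_min": g["longitude"].min() - pad,
            "lon_max": g["longitude"].max() + pad,
            "lat_min": g["latitude"].min() - pad,
            "lat_max": g["latitude"].max() + pad,
        }
    ).reset_index()
    return out


# --------------------------------------------------------------------------
# Contaminant injection


@dataclass(frozen=True)
class ContaminationSpec:
    """Counts of each contaminant class to append per species.

    Mirrors the three record classes the quality-control stage removes:
    exact duplicates, records at herbarium / living-collection
    coordinates, and records displaced outside the species' native box.
    """

    n_duplicates: int = 0
    institution_points: tuple[tuple[float, float], ...] = ()
    n_institution: int = 0
    n_out_of_range: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_duplicates, self.n_institution, self.n_out_of_range) < 0:
            raise ValueError("contaminant counts must be nonnegative")
        if self.n_institution > 0 and not self.institution_points:
            raise ValueError("institution_points required when n_institution > 0")


def inject_contaminants(
    occurrences: pd.DataFrame, native_boxes: pd.DataFrame, spec: ContaminationSpec
) -> pd.DataFrame:
    """Append labelled contaminant records, per species, to a clean set.

    Every input record is labelled ``clean``; appended records carry the
    label of their class (``duplicate``, ``institution``,
    ``out_of_range``).  Duplicate record ids are constructed to sort
    after their originals so duplicate removal retains the clean copy.
    """
    boxes = native_boxes.set_index("species")
    out = [occurrences.assign(label="clean")]
    for species, grp in occurrences.groupby("species", sort=True):
        if species not in boxes.index and (spec.n_out_of_range > 0):
            raise ValueError(f"no native box for species {species!r}")
        rng = _species_rng(spec.seed, str(species), extra=1)
        recs: list[dict] = []
        if spec.n_duplicates > 0:
            pick = rng.choice(len(grp), size=spec.n_duplicates, replace=True)
            for i, k in enumerate(pick):
                src = grp.iloc[k]
                recs.append(
                    {
                        "species": species,
                        "longitude": src["longitude"],
                        "latitude": src["latitude"],
                        "record_id": f"{species}_zdup_{i:03d}",
                        "label": "duplicate",
                    }
                )
        if spec.n_institution > 0:
            for i in range(spec.n_institution):
                lon, lat = spec.institution_points[i % len(spec.institution_points)]
                recs.append(
                    {
                        "species": species,
                        "longitude": lon,
                        "latitude": lat,
                        "record_id": f"{species}_zinst_{i:03d}",
                        "label": "institution",
                    }
                )
        if spec.n_out_of_range > 0:
            box = boxes.loc[species]
            # Displace eastwards into a disjoint region, or westwards if
            # the eastward shift would leave the valid longitude domain.
            shift = 30.0
            east = box["lon_max"] + shift
            base_lon = east if east + 5.0 <= 180.0 else box["lon_min"] - shift - 5.0
            for i in range(spec.n_out_of_range):
                recs.append(
                    {
                        "species": species,
                        "longitude": base_lon + rng.uniform(0.0, 5.0),
                        "latitude": float(
                            np.clip(box["lat_min"] + rng.uniform(-2.0, 2.0), -89.0, 89.0)
                        ),
                        "record_id": f"{species}_zoor_{i:03d}",
                        "label": "out_of_range",
                    }
                )
        if recs:
            out.append(pd.DataFrame(recs))
    return pd.concat(out, ignore_index=True)
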