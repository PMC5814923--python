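"""End-to-end pipeline: clean, extract, summarize, PCA, overlap, EOO, report.

A :class:`PipelineConfig` names the input files and the handful of
parameters the stages expose; :func:`run_pipeline` executes the stages
in order, writes every intermediate table as CSV into a run directory
and records a manifest (parameters, seeds, input checksums, per-stage
record counts) so a rerun with the same config reproduces the outputs
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assoc import run_hypothesis_battery
from .cleaning import clean_occurrences, load_occurrences, DEFAULT_INSTITUTION_TOLERANCE
from .extraction import extract_values, summarize_species, variable_collinearity_screen
from .georange import species_georanges
from .grids import ClimateStack
from .habitat_space import fit_habitat_space, group_hull_area
from .overlap import overlap_table, DEFAULT_OVERLAP_VARIABLES

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters for one reproducible run."""

    raster_dir: str
    occurrences: str
    output_dir: str
    native_regions: str | None = None
    institutions: str | None = None
    genera: str | None = None
    functional_types: str | None = None
    richness: str | None = None
    min_points: int = 3
    institution_tolerance_deg: float = DEFAULT_INSTITUTION_TOLERANCE
    overlap_variables: tuple[str, ...] = DEFAULT_OVERLAP_VARIABLES
    hull_min_species: int = 3
    collinearity_threshold: float = 0.70
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "overlap_variables" in raw:
            raw["overlap_variables"] = tuple(raw["overlap_variables"])
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_optional(path: str | None) -> pd.DataFrame | None:
    return pd.read_csv(path) if path else None


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.

    Halts with a stage-labelled error on any failure.  Outputs:
    ``cleaned.csv``, ``cleaning_report.csv``, ``values.csv``,
    ``summaries.csv``, ``collinearity.csv``, ``space_<kind>_*.csv``,
    ``hulls.csv``, ``overlap.csv``, ``georanges.csv``, ``report.csv``,
    ``report.json`` and ``manifest.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "hydroniche_version": __version__,
        "parameters": {
            k: v for k, v in asdict(config).items() if not isinstance(v, (str, type(None)))
        },
        "inputs": {},
        "stages": {},
    }

    def stage(name):
        logger.info("stage: %s", name)
        return name

    name = stage("load")
    records, rejected = load_occurrences(config.occurrences)
    manifest["inputs"]["occurrences"] = _sha256(config.occurrences)
    manifest["stages"][name] = {"n_records": len(records), "n_rejected": len(rejected)}

    name = stage("clean")
    native = _read_optional(config.native_regions)
    institutions = _read_optional(config.institutions)
    inst_pts = (
        institutions[["longitude", "latitude"]].to_numpy(float) if institutions is not None else ()
    )
    cleaned, report = clean_occurrences(
        records,
        native_regions=native,
        institution_points=inst_pts,
        min_points=config.min_points,
        institution_tolerance_deg=config.institution_tolerance_deg,
    )
    cleaned.to_csv(out / "cleaned.csv", index=False)
    report.to_csv(out / "cleaning_report.csv")
    manifest["stages"][name] = {
        "n_retained": len(cleaned),
        "species_excluded": report.species_excluded,
    }

    name = stage("extract")
    stack = ClimateStack.read_dir(config.raster_dir)
    values, dropped = extract_values(stack, cleaned)
    values.to_csv(out / "values.csv", index=False)
    manifest["stages"][name] = {"n_values": len(values), "n_dropped": len(dropped)}

    name = stage("summarize")
    summaries, excluded = summarize_species(values, min_points=config.min_points)
    summaries.to_csv(out / "summaries.csv", index=False)
    manifest["stages"][name] = {"n_species": len(summaries), "species_excluded": excluded}
    if len(summaries) < 3:
        # Too few species for any multivariate stage; stop after the
        # per-species accounting so the manifest still reports the run.
        logger.warning("fewer than 3 species summarized; multivariate stages skipped")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return out
    screen = variable_collinearity_screen(summaries, threshold=config.collinearity_threshold)
    screen.to_csv(out / "collinearity.csv", index=False)

    name = stage("pca")
    spaces = {}
    for kind in ("position", "range"):
        space = fit_habitat_space(summaries, kind=kind)
        spaces[kind] = space
        space.loadings.to_csv(out / f"space_{kind}_loadings.csv")
        space.scores.to_csv(out / f"space_{kind}_scores.csv", index_label="species")
        pd.DataFrame(
            {"component": space.loadings.columns, "variance_fraction": space.variance_explained}
        ).to_csv(out / f"space_{kind}_variance.csv", index=False)
    manifest["stages"][name] = {
        kind: [round(float(v), 6) for v in spaces[kind].variance_explained]
        for kind in spaces
    }

    genera = _read_optional(config.genera)
    richness = _read_optional(config.richness)
    functional = _read_optional(config.functional_types)

    name = stage("overlap")
    if genera is not None:
        ov = overlap_table(summaries, genera, variables=tuple(config.overlap_variables))
        ov.to_csv(out / "overlap.csv", index=False)
        manifest["stages"][name] = {"n_rows": len(ov)}

    name = stage("georange")
    georanges = species_georanges(cleaned[cleaned["species"].isin(summaries["species"])])
    georanges.to_csv(out / "georanges.csv", index=False)
    manifest["stages"][name] = {"n_species": len(georanges)}

    name = stage("report")
    if genera is not None and richness is not None:
        hulls = pd.concat(
            [
                group_hull_area(spaces[k], genera, min_species=config.hull_min_species)
                for k in spaces
            ],
            ignore_index=True,
        )
        hulls.to_csv(out / "hulls.csv", index=False)
        battery = run_hypothesis_battery(
            summaries,
            georanges,
            spaces["position"],
            spaces["range"],
            genera,
            richness,
            functional_types=functional,
            min_species_per_genus=config.hull_min_species,
        )
        battery.to_frame().to_csv(out / "report.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(
                {
                    "regressions": battery.to_frame().to_dict("records"),
                    "anova_functional_types": battery.anova_functional_types,
                    "sensitivity": battery.sensitivity,
                    "notes": battery.notes,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        manifest["stages"][name] = {"n_regressions": int(battery.to_frame().shape[0])}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
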