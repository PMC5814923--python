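"""Quality control of georeferenced occurrence records.

Automates the manual record-screening steps that precede any habitat
analysis of aggregated museum/herbarium point data: removal of exact
duplicates, of records at herbarium or living-collection coordinates,
and of records falling outside a species' native region, followed by a
minimum-sample-size retention rule (by default three points, the floor
below which a range estimate is meaningless).

Removal order is fixed — duplicates, then institution locations, then
out-of-native-range — so the per-species report counts are unambiguous,
and duplicate resolution keeps the first record by ``record_id`` sort,
which makes the whole stage independent of input record order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("species", "longitude", "latitude", "record_id")

#: Coordinates equal after rounding to this many decimals (~11 m) are
#: treated as the same collection locality.
DUPLICATE_DECIMALS = 4

#: Default radius (degrees) within which a record is attributed to an
#: institution coordinate; absorbs rounding at collection addresses.
DEFAULT_INSTITUTION_TOLERANCE = 0.001


@dataclass
class CleaningReport:
    """Per-species accounting of the cleaning stage.

    ``per_species`` columns: n_input, n_removed_duplicate,
    n_removed_institution, n_removed_outside, n_retained.  The counts
    conserve: n_input = n_retained + all removals.  Species retained
    with fewer than ``min_points`` records are excluded entirely and
    listed in ``species_excluded``.
    """

    per_species: pd.DataFrame
    species_excluded: list[str] = field(default_factory=list)
    species_without_box: list[str] = field(default_factory=list)

    def validate(self) -> None:
        t = self.per_species
        removed = (
            t["n_removed_duplicate"] + t["n_removed_institution"] + t["n_removed_outside"]
        )
        if not (t["n_input"] == t["n_retained"] + removed).all():
            raise AssertionError("cleaning report violates count conservation")

    def to_csv(self, path: str | Path) -> None:
        t = self.per_species.copy()
        t["excluded"] = t["species"].isin(self.species_excluded)
        t.to_csv(path, index=False)


def load_occurrences(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an occurrence CSV, validating coordinates row by row.

    Returns ``(records, rejected)``; rejected rows (missing or
    out-of-bounds coordinates, empty species) keep their 0-based data
    row number in a ``row`` column together with a ``reason``.
    """
    df = pd.read_csv(path, dtype={"species": str, "record_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df.empty:
        logger.warning("%s: empty occurrence file", path)

    lon = pd.to_numeric(df["longitude"], errors="coerce")
    lat = pd.to_numeric(df["latitude"], errors="coerce")
    reasons = pd.Series("", index=df.index)
    bad_coord = ~np.isfinite(lon) | ~np.isfinite(lat)
    reasons[bad_coord] = "missing or non-numeric coordinate"
    out_of_bounds = ~bad_coord & ((lon < -180) | (lon > 180) | (lat < -90) | (lat > 90))
    reasons[out_of_bounds] = "coordinate out of bounds"
    no_species = (reasons == "") & (df["species"].isna() | (df["species"].str.strip() == ""))
    reasons[no_species] = "empty species name"

    bad = reasons != ""
    rejected = df[bad].assign(row=df.index[bad], reason=reasons[bad])
    records = df[~bad].copy()
    records["longitude"] = lon[~bad]
    records["latitude"] = lat[~bad]
    if bad.any():
        logger.warning("%s: rejected %d malformed rows", path, int(bad.sum()))
    return records.reset_index(drop=True), rejected.reset_index(drop=True)


def clean_occurrences(
    records: pd.DataFrame,
    native_regions: pd.DataFrame | None = None,
    institution_points: Sequence[tuple[float, float]] | pd.DataFrame = (),
    min_points: int = 3,
    institution_tolerance_deg: float = DEFAULT_INSTITUTION_TOLERANCE,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the three removal rules and the minimum-sample-size rule.

    Parameters
    ----------
    records
        Occurrence table with the required columns.
    native_regions
        Per-species axis-aligned boxes (``species, lon_min, lon_max,
        lat_min, lat_max``).  Species without a box skip the range rule
        with a logged warning rather than failing.
    institution_points
        Herbarium / living-collection coordinates, as (lon, lat) pairs
        or a table with ``longitude``/``latitude`` columns.
    min_points
        Species retaining fewer records than this are excluded entirely.
    institution_tolerance_deg
        Euclidean degree radius for the institution match; 0 means
        exact coordinate equality.
    """
    if min_points < 1:
        raise ValueError("min_points must be at least 1")
    if isinstance(institution_points, pd.DataFrame):
        inst = institution_points[["longitude", "latitude"]].to_numpy(float)
    else:
        inst = np.asarray(list(institution_points), float).reshape(-1, 2)
    boxes = (
        native_regions.set_index("species") if native_regions is not None else pd.DataFrame()
    )
    if not boxes.empty:
        bad = (boxes["lon_min"] > boxes["lon_max"]) | (boxes["lat_min"] > boxes["lat_max"])
        if bad.any():
            raise ValueError(f"inverted native boxes for: {list(boxes.index[bad])}")

    work = records.sort_values(["species", "record_id"], kind="mergesort").reset_index(drop=True)

    # Rule 1: exact duplicates (species + rounded coordinates), first
    # record by record_id sort wins.
    key_lon = work["longitude"].round(DUPLICATE_DECIMALS)
    key_lat = work["latitude"].round(DUPLICATE_DECIMALS)
    dup = pd.Series(
        pd.DataFrame({"s": work["species"], "x": key_lon, "y": key_lat}).duplicated().to_numpy(),
        index=work.index,
    )

    # Rule 2: records at institution coordinates.
    if len(inst):
        d2 = (
            (work["longitude"].to_numpy()[:, None] - inst[:, 0]) ** 2
            + (work["latitude"].to_numpy()[:, None] - inst[:, 1]) ** 2
        )
        at_inst = pd.Series((d2 <= institution_tolerance_deg**2).any(axis=1), index=work.index)
    else:
        at_inst = pd.Series(False, index=work.index)
    at_inst &= ~dup

    # Rule 3: outside the species' native region.
    outside = pd.Series(False, index=work.index)
    no_box: list[str] = []
    for species, grp in work.groupby("species", sort=False):
        if boxes.empty or species not in boxes.index:
            if not boxes.empty:
                no_box.append(str(species))
            continue
        b = boxes.loc[species]
        out = (
            (grp["longitude"] < b["lon_min"])
            | (grp["longitude"] > b["lon_max"])
            | (grp["latitude"] < b["lat_min"])
            | (grp["latitude"] > b["lat_max"])
        )
        outside.loc[grp.index] = out
    if no_box:
        logger.warning("no native box for %d species; range rule skipped", len(no_box))
    outside &= ~dup & ~at_inst

    keep = ~(dup | at_inst | outside)
    counts = pd.DataFrame(
        {
            "species": work["species"],
            "dup": dup,
            "inst": at_inst,
            "outside": outside,
            "keep": keep,
        }
    ).groupby("species", sort=True)
    report_table = pd.DataFrame(
        {
            "n_input": counts.size(),
            "n_removed_duplicate": counts["dup"].sum().astype(int),
            "n_removed_institution": counts["inst"].sum().astype(int),
            "n_removed_outside": counts["outside"].sum().astype(int),
            "n_retained": counts["keep"].sum().astype(int),
        }
    ).reset_index()

    excluded = report_table.loc[report_table["n_retained"] < min_points, "species"].tolist()
    retained = work[keep & ~work["species"].isin(excluded)].reset_index(drop=True)

    report = CleaningReport(
        per_species=report_table, species_excluded=excluded, species_without_box=no_box
    )
    report.validate()
    return retained, report
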