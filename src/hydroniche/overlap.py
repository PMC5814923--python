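"""Within-group pairwise habitat-interval overlap statistics.

For a chosen indicator variable, each species occupies the interval
[min, max] observed over its presence points.  The overlap between two
species is the absolute length of the intersection of their intervals,

    overlap(i, j) = max(0, min(max_i, max_j) - max(min_i, min_j)),

and a taxonomic group is summarized by the mean and standard deviation
of this quantity over all unordered pairs of its species.  Because a
group of wide-ranging species overlaps more in absolute terms for
purely geometric reasons, the mean overlap is normalized by the group's
mean species-level range; the resulting dimensionless ratio lies in
[0, 1] and is comparable across groups and variables.

The group mean and SD are taken over the off-diagonal unordered pairs:
the diagonal of the pairwise matrix holds each species' own range, a
within-species quantity that does not belong in a between-species
overlap statistic.  A flag restores the full-matrix convention for
sensitivity checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Variables used for overlap analysis by default; the other indicators
#: are strongly collinear with these.
DEFAULT_OVERLAP_VARIABLES = ("AI", "P_seas")


def pairwise_overlap_matrix(summaries: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Symmetric species-by-species interval overlap matrix.

    The diagonal holds each species' own range (a species fully
    overlaps itself).  Requires at least two species with valid
    ``<variable>_min``/``<variable>_max`` columns.
    """
    lo = summaries[f"{variable}_min"].to_numpy(float)
    hi = summaries[f"{variable}_max"].to_numpy(float)
    if len(lo) < 2:
        raise ValueError("pairwise overlap requires at least 2 species")
    if np.any(lo > hi):
        bad = summaries["species"][lo > hi].tolist()
        raise ValueError(f"species with min > max for {variable}: {bad}")
    ov = np.minimum(hi[:, None], hi[None, :]) - np.maximum(lo[:, None], lo[None, :])
    ov = np.maximum(ov, 0.0)
    names = summaries["species"].to_numpy()
    return pd.DataFrame(ov, index=names, columns=names)


def group_overlap_summary(
    matrix: pd.DataFrame,
    summaries: pd.DataFrame,
    variable: str,
    group: str = "",
    include_diagonal: bool = False,
) -> dict:
    """Mean/SD pairwise overlap and its range-normalized value.

    ``normalized_overlap`` is the mean pairwise overlap divided by the
    arithmetic mean of species ranges in the group; it is undefined
    (NaN) when the mean range is zero.
    """
    ov = matrix.to_numpy(float)
    n = ov.shape[0]
    if include_diagonal:
        vals = ov[np.triu_indices(n, k=0)]
    else:
        vals = ov[np.triu_indices(n, k=1)]
    ranges = (
        summaries[f"{variable}_max"] - summaries[f"{variable}_min"]
    ).to_numpy(float)
    mean_range = float(ranges.mean())
    mean_ov = float(vals.mean())
    normalized = mean_ov / mean_range if mean_range > 0 else float("nan")
    return {
        "group": group,
        "variable": variable,
        "n_species": n,
        "mean_pairwise_overlap": mean_ov,
        "sd_pairwise_overlap": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        "mean_species_range": mean_range,
        "normalized_overlap": normalized,
    }


def overlap_table(
    summaries: pd.DataFrame,
    groups: pd.DataFrame,
    variables: tuple[str, ...] = DEFAULT_OVERLAP_VARIABLES,
    include_diagonal: bool = False,
) -> pd.DataFrame:
    """Overlap summaries for every group x variable combination.

    ``groups`` maps ``species`` to ``group``; groups with fewer than two
    summarized species are skipped.
    """
    merged = summaries.merge(groups, on="species", how="inner")
    rows = []
    for group, grp in merged.groupby("group", sort=True):
        if len(grp) < 2:
            continue
        for var in variables:
            m = pairwise_overlap_matrix(grp, var)
            rows.append(
                group_overlap_summary(m, grp, var, group=str(group), include_diagonal=include_diagonal)
            )
    return pd.DataFrame(rows)
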