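"""Multivariate climate spaces from species habitat summaries.

Species-level indicator values (means for *position space*, ranges for
*range space*) are log-transformed as log10(x + 1), standardized to
zero mean and unit variance, and decomposed by PCA.  The first two
principal components define the climate space in which species scores
are compared; the diversity of a genus (or any other grouping) in that
space is the area of the smallest convex hull covering its species
scores, computed for groups of three or more species.

The log offset of 1 accommodates exact zeros (a species' driest-month
precipitation, or any range when all points share a cell); the
unit-variance scaling puts the five heterogeneous-unit indicators on a
common footing (PCA on the correlation structure).  Component signs are
fixed so each component's largest-magnitude loading is positive, which
makes score plots reproducible across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from sklearn.decomposition import PCA

from .grids import INDICATORS

logger = logging.getLogger(__name__)

LOG_OFFSET = 1.0


@dataclass
class HabitatSpace:
    """A fitted PCA climate space (position or range kind)."""

    kind: str  # "position" or "range"
    variables: list[str]
    log_offset: float
    center: np.ndarray  # per-variable mean of the log-transformed data
    scale: np.ndarray  # per-variable sd of the log-transformed data
    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame  # species x components, indexed by species
    variance_explained: np.ndarray  # fractions, sum to 1

    def transform(self, summaries: pd.DataFrame) -> pd.DataFrame:
        """Project new species summaries into the fitted space."""
        X = _design_matrix(summaries, self.kind, self.variables, self.log_offset)
        Z = (X - self.center) / self.scale
        scores = Z @ self.loadings.to_numpy()
        return pd.DataFrame(
            scores, index=summaries["species"], columns=self.loadings.columns
        )


def _design_matrix(
    summaries: pd.DataFrame, kind: str, variables: list[str], log_offset: float
) -> np.ndarray:
    suffix = {"position": "_mean", "range": "_range"}[kind]
    cols = [f"{v}{suffix}" for v in variables]
    X = summaries[cols].to_numpy(float)
    if not np.all(np.isfinite(X)):
        raise ValueError("habitat summaries contain non-finite values")
    return np.log10(X + log_offset)


def fit_habitat_space(
    summaries: pd.DataFrame,
    kind: str = "position",
    variables: tuple[str, ...] = INDICATORS,
    log_offset: float = LOG_OFFSET,
) -> HabitatSpace:
    """Fit the PCA climate space of the given kind.

    Parameters
    ----------
    summaries
        Species habitat summary table (one row per species with
        ``<var>_mean`` and ``<var>_range`` columns).
    kind
        ``"position"`` decomposes species means, ``"range"`` species
        ranges.
    """
    if kind not in ("position", "range"):
        raise ValueError("kind must be 'position' or 'range'")
    if len(summaries) < 3:
        raise ValueError("PCA requires at least 3 species")
    variables = list(variables)
    X = _design_matrix(summaries, kind, variables, log_offset)
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    zero_var = [v for v, p in zip(variables, np.ptp(X, axis=0)) if p == 0]
    if zero_var:
        raise ValueError(f"zero variance after log transform for: {zero_var}")
    Z = (X - center) / scale

    # rank cannot exceed the species count; cap components accordingly
    k = min(len(variables), len(summaries))
    pca = PCA(n_components=k)
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T  # variables x components, orthonormal columns

    # Fix the sign indeterminacy of each component.
    for j in range(k):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0

    comp_names = [f"PC{j + 1}" for j in range(k)]
    return HabitatSpace(
        kind=kind,
        variables=variables,
        log_offset=log_offset,
        center=center,
        scale=scale,
        loadings=pd.DataFrame(loadings, index=variables, columns=comp_names),
        scores=pd.DataFrame(scores, index=summaries["species"].to_numpy(), columns=comp_names),
        variance_explained=pca.explained_variance_ratio_,
    )


def hull_area_2d(points: np.ndarray) -> float:
    """Convex-hull area of 2D points; 0 for degenerate (collinear) sets."""
    pts = np.unique(np.asarray(points, float).reshape(-1, 2), axis=0)
    if len(pts) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2D "volume" is area
    except QhullError:
        return 0.0


def group_hull_area(
    space: HabitatSpace, groups: pd.DataFrame, min_species: int = 3
) -> pd.DataFrame:
    """Convex-hull area of each group's species scores in PC1-PC2.

    ``groups`` maps ``species`` to ``group``; groups with fewer than
    ``min_species`` scored species are omitted with a log entry.
    Returns ``group, n_species, hull_area, kind``.
    """
    assignment = groups.set_index("species")["group"]
    scores = space.scores[["PC1", "PC2"]]
    rows = []
    skipped = []
    for group, members in assignment.groupby(assignment):
        sp = members.index.intersection(scores.index)
        if len(sp) < min_species:
            skipped.append(str(group))
            continue
        rows.append(
            {
                "group": group,
                "n_species": len(sp),
                "hull_area": hull_area_2d(scores.loc[sp].to_numpy()),
                "kind": space.kind,
            }
        )
    if skipped:
        logger.info("group_hull_area: skipped %d groups below %d species", len(skipped), min_species)
    return pd.DataFrame(rows)
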