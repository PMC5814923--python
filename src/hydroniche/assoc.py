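"""Hypothesis batteries linking habitat, geography and diversity.

The batteries test, on whatever species cohort is supplied:

* position vs. range — per indicator, does a species' habitat position
  predict its habitat range (e.g. are dry-adapted species more
  specialized)?
* habitat range vs. geographic range — per indicator, does climatic
  tolerance predict log extent of occurrence?
* richness vs. climate-space diversity — across genera with three or
  more species, do larger genera cover more of the position and range
  PC spaces, and do the two kinds of diversity track each other?
* a one-way ANOVA of log range size across functional types; and
* a sample-size sensitivity screen correlating the number of presence
  points used per species with each estimated range.

All regressions are ordinary least squares; where a log transform is
applied it is log10(v + 1) so zero ranges and zero areas are handled
uniformly.  p values are reported raw (no multiplicity correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grids import INDICATORS
from .habitat_space import HabitatSpace, group_hull_area

logger = logging.getLogger(__name__)


@dataclass
class RegressionResult:
    label: str
    n: int
    slope: float
    intercept: float
    r2: float
    p_value: float
    log_x: bool = False
    log_y: bool = False

    @property
    def sign(self) -> str:
        return "+" if self.slope >= 0 else "-"

    def asdict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "p_value": self.p_value,
            "sign": self.sign,
            "log_x": self.log_x,
            "log_y": self.log_y,
        }


def linear_regression(
    x, y, log_x: bool = False, log_y: bool = False, label: str = ""
) -> RegressionResult | None:
    """OLS of y on x with optional log10(v + 1) transforms.

    Returns ``None`` (a missing result) when x has zero variance, since
    the slope is then undefined.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"regression {label!r}: need at least 3 finite pairs")
    if log_x:
        x = np.log10(x + 1.0)
    if log_y:
        y = np.log10(y + 1.0)
    if np.ptp(x) == 0:
        logger.warning("regression %r: zero variance in x; result undefined", label)
        return None
    if np.ptp(y) == 0:
        # a constant response is a defined (null) fit, not a missing one
        return RegressionResult(
            label=label, n=len(x), slope=0.0, intercept=float(y[0]),
            r2=0.0, p_value=1.0, log_x=log_x, log_y=log_y,
        )
    fit = stats.linregress(x, y)
    return RegressionResult(
        label=label,
        n=len(x),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        log_x=log_x,
        log_y=log_y,
    )


def anova_oneway(groups: dict[str, np.ndarray]) -> dict:
    """One-way fixed-effects ANOVA across labelled groups.

    Groups with fewer than two values are excluded with a warning.
    Returns F, p, and per-group means and sizes.
    """
    usable = {k: np.asarray(v, float) for k, v in groups.items() if len(v) >= 2}
    dropped = sorted(set(groups) - set(usable))
    if dropped:
        logger.warning("anova: excluded groups with <2 values: %s", dropped)
    if len(usable) < 2:
        raise ValueError("ANOVA requires at least 2 groups with >=2 values each")
    f, p = stats.f_oneway(*usable.values())
    return {
        "F": float(f),
        "p_value": float(p),
        "group_means": {k: float(v.mean()) for k, v in usable.items()},
        "group_sizes": {k: int(len(v)) for k, v in usable.items()},
        "excluded_groups": dropped,
    }


@dataclass
class HypothesisReport:
    """All batteries, keyed the way the pipeline report writes them."""

    position_vs_range: list[RegressionResult | None] = field(default_factory=list)
    georange_vs_range: list[RegressionResult | None] = field(default_factory=list)
    richness_diversity: list[RegressionResult | None] = field(default_factory=list)
    anova_functional_types: dict | None = None
    sensitivity: dict[str, float] = field(default_factory=dict)
    notes: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for battery, results in (
            ("position_vs_range", self.position_vs_range),
            ("georange_vs_range", self.georange_vs_range),
            ("richness_diversity", self.richness_diversity),
        ):
            for r in results:
                if r is not None:
                    rows.append({"battery": battery, **r.asdict()})
        return pd.DataFrame(rows)


def run_hypothesis_battery(
    summaries: pd.DataFrame,
    georanges: pd.DataFrame,
    position_space: HabitatSpace,
    range_space: HabitatSpace,
    genera: pd.DataFrame,
    richness: pd.DataFrame,
    functional_types: pd.DataFrame | None = None,
    min_species_per_genus: int = 3,
) -> HypothesisReport:
    """Run every battery on one coherent species cohort.

    Parameters
    ----------
    summaries, georanges
        Species habitat summaries and EOO areas, on the same species.
    position_space, range_space
        Fitted PCA spaces of both kinds for the cohort.
    genera
        ``species, group`` table assigning species to genera.
    richness
        ``group, richness`` table of known species richness per genus.
    functional_types
        Optional ``species, functional_type`` table; enables the
        range-size ANOVA.
    """
    report = HypothesisReport()
    report.notes["multiple_testing"] = "none; raw p values"

    # Battery: habitat position vs. habitat range, untransformed.
    for var in INDICATORS:
        report.position_vs_range.append(
            linear_regression(
                summaries[f"{var}_mean"],
                summaries[f"{var}_range"],
                label=f"{var}_range ~ {var}_mean",
            )
        )

    # Battery: log geographic range size vs. habitat range.
    merged = summaries.merge(georanges, on="species", how="inner")
    for var in INDICATORS:
        report.georange_vs_range.append(
            linear_regression(
                merged[f"{var}_range"],
                merged["area_km2"],
                log_y=True,
                label=f"log10(area_km2+1) ~ {var}_range",
            )
        )

    # Battery: richness vs. PC-space hull diversity across genera.
    pos_hulls = group_hull_area(position_space, genera, min_species=min_species_per_genus)
    rng_hulls = group_hull_area(range_space, genera, min_species=min_species_per_genus)
    hulls = pos_hulls.merge(
        rng_hulls, on="group", suffixes=("_position", "_range")
    ).merge(richness, on="group", how="left")
    missing = hulls["group"][hulls["richness"].isna()].tolist()
    if missing:
        logger.warning("richness missing for genera %s; dropped", missing)
        hulls = hulls.dropna(subset=["richness"])
    report.notes["genera_used"] = hulls["group"].tolist()
    if len(hulls) >= 3:
        report.richness_diversity = [
            linear_regression(
                hulls["hull_area_position"],
                hulls["richness"],
                log_x=True,
                log_y=True,
                label="log10(richness) ~ log10(position_hull_area)",
            ),
            linear_regression(
                hulls["hull_area_range"],
                hulls["richness"],
                log_x=True,
                log_y=True,
                label="log10(richness) ~ log10(range_hull_area)",
            ),
            linear_regression(
                hulls["hull_area_position"],
                hulls["hull_area_range"],
                label="range_hull_area ~ position_hull_area",
            ),
        ]

    # Battery: range-size ANOVA across functional types (log scale; EOO
    # distributions are heavy-tailed).
    if functional_types is not None:
        ft = georanges.merge(functional_types, on="species", how="inner")
        groups = {
            str(k): np.log10(v["area_km2"].to_numpy(float) + 1.0)
            for k, v in ft.groupby("functional_type")
        }
        report.anova_functional_types = anova_oneway(groups)

    # Sensitivity: does sample size drive the estimated ranges?
    n_used = summaries["n_points_used"].to_numpy(float)
    for var in INDICATORS:
        rng_vals = summaries[f"{var}_range"].to_numpy(float)
        if np.ptp(n_used) == 0 or np.ptp(rng_vals) == 0:
            report.sensitivity[var] = float("nan")
        else:
            report.sensitivity[var] = float(stats.pearsonr(n_used, rng_vals).statistic)
    return report
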