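"""Fit the PCA climate spaces and measure group diversity as hull area.

Species means (position space) or ranges (range space) of the five
indicators are log10(x+1)-transformed, standardized and decomposed;
the convex-hull area of a genus' scores in PC1-PC2 measures how much
of the climate space its species cover.
"""

import pandas as pd

from hydroniche import fit_habitat_space, group_hull_area
from hydroniche.studies import two_block_summaries

# Summaries with a known two-factor structure: a moisture factor behind
# MAP/AI/AET_PET and a seasonality factor behind P_seas/P_dry.
summaries = two_block_summaries(seed=0, n_species=120)

space = fit_habitat_space(summaries, kind="position")
pc1, pc2 = space.variance_explained[:2] * 100
print(f"PC1 explains {pc1:.1f}% of variance, PC2 {pc2:.1f}% (two dominant axes)")
print("\nloadings (each variable aligns with its block's component):")
print(space.loadings[["PC1", "PC2"]].round(2))

groups = pd.DataFrame(
    {"species": summaries["species"], "group": ["GenA", "GenB", "GenC"] * 40}
)
hulls = group_hull_area(space, groups, min_species=3)
print("\nper-group climate-space hull areas (squared score units):")
print(hulls.round(2).to_string(index=False))
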