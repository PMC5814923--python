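"""Small published reference tables bundled with the package.

These are printed group-level summary statistics from the published
terrestrial-bromeliad hydrological habitat analysis; they are inputs
for consistency checks (e.g. verifying that the overlap normalization
reproduces the printed normalized column), not outputs of this package.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

# Group-level mean pairwise species range overlap for the aridity index
# (AI, stored in the x1e4 scaled-integer convention) and precipitation
# seasonality (P_seas, %), with group mean species-level ranges and the
# printed range-normalized overlap, across eight terrestrial bromeliad
# taxonomic groups.
_BROMELIAD_OVERLAP_CSV = """\
group,n_species,variable,mean_pairwise_overlap,mean_species_range,normalized_overlap
Brocchinioideae-Lindmanioideae,25,AI,403.49,5911.66,0.068
Hechtioideae,26,AI,106.34,5026.96,0.021
Navioideae,28,AI,826.78,4710.64,0.176
Pitcairnia-Fosterella,208,AI,509.97,10187.66,0.050
Xeric Clade,79,AI,554.83,3955.18,0.140
Puyoideae,99,AI,499.21,7549.20,0.066
C3 early-diverging Bromelioideae,22,AI,87.88,12449.85,0.007
CAM early-diverging Bromelioideae,77,AI,252.93,5551.77,0.046
Brocchinioideae-Lindmanioideae,25,P_seas,1.960,21.86,0.090
Hechtioideae,26,P_seas,1.800,18.40,0.098
Navioideae,28,P_seas,1.260,16.65,0.076
Pitcairnia-Fosterella,208,P_seas,4.210,32.94,0.128
Xeric Clade,79,P_seas,6.321,23.33,0.271
Puyoideae,99,P_seas,3.594,31.10,0.116
C3 early-diverging Bromelioideae,22,P_seas,1.083,36.54,0.030
CAM early-diverging Bromelioideae,77,P_seas,2.320,29.13,0.080
"""


def bromeliad_overlap_reference() -> pd.DataFrame:
    """Published group-level overlap summaries for terrestrial bromeliads."""
    return pd.read_csv(StringIO(_BROMELIAD_OVERLAP_CSV))
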