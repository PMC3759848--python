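"""Structure-volume vs behaviour correlation table.

Pearson correlations between per-subject ROI volumes and behavioural
scores, Bonferroni-corrected across the table, with a weak/medium/strong
banding of |r| (boundaries at 0.3 and 0.7).
"""

import pandas as pd

from strokemap import SyntheticConfig, generate_cohort
from strokemap.deformation import roi_volume
from strokemap.stats import roi_behaviour_correlations

cohort = generate_cohort(SyntheticConfig(
    seed=11, n_sham=10, n_striatal=10, n_striatal_cortical=10,
    make_fields=False, make_images=False,
))

vols = pd.DataFrame(
    {"lesion": [roi_volume(s.lesion_mask, cohort.voxel_dims_mm)
                for s in cohort.subjects]},
    index=[s.subject_id for s in cohort.subjects],
)
beh = cohort.behaviour_table().drop(columns=["group"])

table = roi_behaviour_correlations(vols, beh, alpha=0.05)
print(table.to_string(index=False))
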