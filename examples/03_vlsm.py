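"""Voxel lesion-symptom mapping on a phantom cohort.

At each voxel, subjects are split by lesion presence and their foot-fault
scores compared with a Welch t-test; significance comes from permuting the
scores and correcting with the false discovery rate.  Voxels without five
subjects on each side are reported as untested, not as non-significant.
"""

import numpy as np

from strokemap import SyntheticConfig, VLSMConfig, generate_cohort, vlsm_inference, vlsm_tmap
from strokemap.stats import PermutationConfig

cohort = generate_cohort(SyntheticConfig(
    seed=208, n_sham=15, n_striatal=15, n_striatal_cortical=0,
    make_fields=False, make_images=False,
))
masks, scores = cohort.lesion_masks(), cohort.scores("ffl")

cfg = VLSMConfig(min_group_size=5,
                 permutation=PermutationConfig(n_permutations=9999, seed=0))
result = vlsm_tmap(masks, scores, cohort.brain_mask, cfg)
result = vlsm_inference(result, masks, scores, cfg)

n_brain = int(cohort.brain_mask.sum())
print(f"brain voxels:        {n_brain}")
print(f"testable voxels:     {int(result.tested.sum())} "
      f"(lesion and no-lesion groups both >= 5)")
print(f"max |t|:             {np.nanmax(np.abs(result.t_map)):.2f}")
print(f"FDR-significant:     {int(result.significant.sum())} voxels (q = 0.05)")

region = np.asarray(cohort.ground_truth["template_striatal"])
inside = (result.significant & region).sum()
print(f"of which inside the true coupled region: {inside}")
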