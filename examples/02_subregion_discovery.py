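"""Two-stage habitat discovery on a synthetic cohort.

Stage 1 oversegments each window-normalized lesion into SLIC supervoxels;
stage 2 clusters the pooled supervoxel mean intensities with a Gaussian
mixture, choosing the subregion count by the elbow of the SSE curve.
"""

import numpy as np
import pandas as pd

from habitatmsi.preprocessing import crop_voi, window_normalize
from habitatmsi.subregions import (
    assign_subregions,
    compute_supervoxels,
    fit_subregion_model,
    subregion_stats,
)
from habitatmsi.synthetic import CohortRecipe, generate_cohort

cohort = generate_cohort(CohortRecipe(n_train=30, n_val=4, n_test=4, seed=5))

svmaps, hu_vols = [], []
for vol, mask in zip(cohort.volumes, cohort.masks):
    vol_c, mask_c = crop_voi(vol, mask, margin_vox=2)
    svmaps.append(compute_supervoxels(window_normalize(vol_c), mask_c))
    hu_vols.append(vol_c)

train = np.flatnonzero((cohort.table["cohort"] == "train").to_numpy())
pooled = pd.concat([svmaps[i].phenotypes for i in train], ignore_index=True)
model = fit_subregion_model(pooled, k_candidates=range(1, 7), seed=5)

print(f"pooled supervoxels: {len(pooled)}")
print("SSE per candidate k:", {k: round(v, 2) for k, v in model.sse_curve.items()})
print(f"elbow-selected k = {model.k}")
print("canonical subregion means (unit scale):", model.canonical_means().round(3))

stats = subregion_stats(assign_subregions(svmaps[0], model), hu_vols[0])
print("\nfirst lesion, per-subregion stats:")
print(stats.round(2))
print(
    "\nSubregion 1 is the densest habitat (highest HU), subregion 2 the most\n"
    "air-like, subregion 3 intermediate - consistent across all cohorts\n"
    "because one cohort-level model labels every lesion."
)
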