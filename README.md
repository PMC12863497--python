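# habitatmsi

Intratumoral spatial-heterogeneity analysis for CT lung nodules: density-based
**habitat (subregion) discovery**, **multi-regional spatial interaction (MSI)**
feature extraction, and a complete **grade-prediction modeling harness** —
exercised end-to-end on seeded synthetic nodule cohorts.

## The problem

Invasive pulmonary adenocarcinoma is graded histologically (low vs high
grade), and conventional radiomics treats the tumor as a homogeneous whole,
masking the internal architecture that distinguishes aggressive lesions.
This package quantifies that architecture in three steps:

1. **Subregion discovery.** Each lesion (HU volume + mask) is
   window-normalized (width 1500 HU, level −600 HU → [−1350, 150] mapped to
   [0, 1]) and oversegmented into SLIC supervoxels (`n_segments = 100`).
   Supervoxel mean intensities are pooled over the *training* cohort and
   clustered with a 1-D Gaussian mixture; the number of subregions k is the
   elbow of the hard-assignment SSE curve. Canonical labels: subregion 1 =
   highest attenuation (dense, sub-solid tissue, ≈ −72.6 HU), subregion 2 =
   lowest (air-like/lepidic, ≈ −827 HU), subregion 3 = intermediate
   (≈ −424 HU).

2. **MSI features.** For every face-adjacent voxel pair touching the lesion,
   the pair of labels (0 = background, 1..k) votes into a symmetric
   (k+1)×(k+1) co-occurrence matrix N. Diagonal cells scale with subregion
   volume, off-diagonal cells count inter-region border contacts
   (B = Σ_{i<j} N(i,j)). From N the extractor derives **33 first-order**
   features (volume proportions, border proportions
   `MSI_border_proportion_i_j = N(i,j)/B`, conditional border proportions,
   boundary shares, interior ratios, pair count/entropy, extrema) and **5
   second-order** Haralick-style statistics on P = N/ΣN (contrast,
   correlation, energy, homogeneity, entropy).

3. **Modeling harness.** SMOTE rebalancing of the training cohort
   (perc.over = 200, perc.under = 155), train-fitted z-scores, RFE +
   L1-logistic feature selection with 10-fold CV, a 4 preprocessor × 5
   classifier grid ranked on validation AUC, and evaluation: DeLong-variance
   AUC CIs and paired tests, calibration/Brier, decision-curve net benefit,
   diameter subgroups, exact Shapley attribution, and the proportion sample
   size formula n = ⌈Z² P(1−P)/Δ²⌉.

Because no imaging cohort of this kind is redistributable, the
`synthetic` module is a first-class component: it generates nodules as
spatially coherent three-component mixtures whose composition shifts with
grade (high grade: dense fraction 0.62 vs 0.18, peripheralized air-like
tissue), plus a Table-1-style covariate table with ~18.6 % high-grade
prevalence split 161/66/128 into train/validation/test.

## Worked example

```python
from habitatmsi.pipeline import run_msi_experiment
from habitatmsi.synthetic import CohortRecipe

res = run_msi_experiment(CohortRecipe(n_train=48, n_val=16, n_test=16, seed=3), seed=3)
print(res["subregion_model"].k)        # 3  (elbow-selected habitat count)
r = res["reports"]["test"]
print(round(r.auc, 3), round(r.brier, 3))
```

Running `python examples/04_grade_model.py` prints (among other lines):

```
subregions selected: k = 3
best candidate: box_cox + random_forest
train: AUC 1.000 (1.000-1.000)  sens 1.00  spec 1.00  brier 0.002
  val: AUC 1.000 (1.000-1.000)  sens 0.67  spec 1.00  brier 0.005
 test: AUC 1.000 (1.000-1.000)  sens 1.00  spec 1.00  brier 0.004
```

k = 3 is the recovered habitat count; the near-perfect AUC reflects the
strong grade effect the generator encodes, not the difficulty of real
cohorts. The other scripts in `examples/` walk through cohort generation,
subregion discovery, the MSI matrix on a toy label map, and the statistics
toolbox individually.

A thin CLI mirrors the pipeline for shell use
(`habitat simulate|preprocess|samplesize|compare|run`); the Python API is
the primary interface.

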