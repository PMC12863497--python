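# Methods

This note documents the models, conventions and numerical choices behind
`habitatmsi`, and what the synthetic cohorts do and do not establish.

## Synthetic nodule generator

The generator emulates the statistical structure the analysis assumes rather
than CT physics. A nodule is a sphere (radius = diameter/2 per axis in
voxels) with a smooth radial perturbation (amplitude 0.12 of the radius,
correlation length = `interface_scale`), post-processed to a single
6-connected, hole-free component. In-mask voxels are partitioned into three
density components by ranking a Gaussian-smoothed random field and cutting
at the target-fraction quantiles, so realized fractions match targets to
within one voxel. The field is optionally biased by depth (distance to the
lesion surface, weight `peripheral_air_weight`): the low tail of the field —
assigned to the air-like component — then sits at the periphery, and the
dense component at the core.

Component attenuations are Normal(mean, sd) per voxel with canonical means
−72.6 / −827.25 / −424.05 HU (dense / air-like / intermediate) and sds
90 / 110 / 120 HU, a spread chosen to represent tissue heterogeneity plus
scanner noise while keeping the three phenotypes resolvable at supervoxel
scale. Background lung is Normal(−850, 20) HU.

Grade defaults encode the observed direction of effect: volume fractions
(dense, air, intermediate) = (0.18, 0.12, 0.70) for low grade and
(0.62, 0.03, 0.35) for high grade, anchored to reported exemplar lesions
(low: 16/6/78 %, high: 74/0/26 %); per-case fractions are Dirichlet-jittered
(concentration 30) around the grade target, giving inter-patient sds of
roughly 0.07–0.09. `peripheral_air_weight` is 1.5 for high grade
(consolidated growth displacing aerated tissue outward) and 0.3 for low
grade. `interface_scale` defaults to 3 mm — no quantitative interface
statistic was available to anchor it, so it is a one-time realism choice: a
correlation length comparable to a few supervoxels yields contiguous
habitats rather than salt-and-pepper mixing.

Cohort structure: 161/66/128 cases (train/validation/test) at high-grade
prevalence 0.186; each cohort receives exactly `round(prevalence × n)`
high-grade cases, which reproduces 66/355 = 18.6 % overall. Covariates are
drawn independently per grade from categorical/normal/lognormal marginals
matching a typical baseline table; covariate correlations are deliberately
not modeled. All randomness descends from one master seed through named
`SeedSequence` child streams (assignment, covariates, one stream per image),
so cohorts are byte-identical across runs and components can be regenerated
independently.

What passing tests on these cohorts show: the pipeline's bookkeeping,
determinism, leakage guards, and that the method recovers structure it is
designed to detect. What they do not show: performance on real CT, where
component contrasts are weaker, masks are imperfect, and scanner effects
correlate features with sites.

## Preprocessing

Window normalization clips HU to [level − width/2, level + width/2]
(defaults [−1350, 150]) and maps the window affinely to [0, 1]; saturation
is what makes "max-min after windowing" well defined. Resampling uses cubic
B-splines for intensities and nearest-neighbour for masks, with output
dimensions `round(dim × spacing / target)`. Subregion analysis runs on the
1 mm isotropic grid by default (`resample_iso_mm=None` disables it, keeping
the native grid). Empty∩empty Dice is defined as 1.

## Subregion discovery

The supervoxel phenotype is the scalar mean normalized intensity — the
minimal choice consistent with density-based clustering; the phenotype table
is extensible. SLIC runs on the masked VOI with compactness 0.1 on the unit
intensity scale and enforced connectivity; labels are restricted to in-mask
voxels and relabelled densely 1..S.

The cohort mixture is a full-covariance 1-D Gaussian mixture (10 restarts,
tol 1e-6, reg_covar 1e-9, ≤500 iterations, seeded). The model-selection SSE
is the within-cluster sum of squared phenotype deviations under hard
maximum-posterior assignment — the mixture log-likelihood is monotone in k
and has no natural elbow scale. EM local optima can make that curve tick
upward at some k; a running minimum is applied before elbow selection and
the correction is flagged on the model (`sse_monotonized`).

**Elbow criterion.** The selected k maximizes the second difference of
log-SSE over interior candidates, ties toward smaller k. The log scale makes
the criterion scale-invariant: with clusters of unequal separation the raw
second difference is dominated by the first large drop and systematically
returns k=2 even for three well-resolved components, whereas log-curvature
finds the last drop that is large *relative to the remaining error*. A curve
that is flat at zero (constant data) returns the smallest candidate.

Canonical labels fix subregion semantics across cohorts: 1 = highest mean
attenuation, 2 = lowest, 3..k = remaining in descending attenuation. This
keeps named features such as `MSI_border_proportion_2_3` meaningful
regardless of the mixture's internal component order; relabeling is
invariant to component permutation (tested).

## MSI matrix and features

Connectivity defaults to 6 (face adjacency — "border" means face contact);
26-connectivity is available for sensitivity analysis. Pairs wholly in
background are excluded, so N(0,0) = 0 and the matrix describes the lesion
and its immediate interface. Counts are voxel-pair counts on the label-map
grid, not mm² surface areas. Proportion features of absent regions follow a
0/0 → 0 convention with per-feature degeneracy flags. Second-order features
use the integer labels 0..k as gray levels on P = N/ΣN, the standard
co-occurrence convention; a zero marginal variance defines correlation as 0.

The first-order enumeration (33 names) comprises: 3 volume proportions, the
background interface fraction, 6 unordered border proportions, 12 ordered
conditional border proportions p(j|i), 4 region boundary shares, 3 interior
ratios, the present-pair count, the pair entropy, and the volume-proportion
extrema. The second-order set is contrast, correlation, energy, homogeneity
and entropy — the standard co-occurrence quintet accompanying the two named
statistics the analysis emphasizes.

## Modeling harness

SMOTE follows the perc.over/perc.under convention of its parameter names
(documented because two software traditions disagree): each minority case
spawns ⌊perc.over/100⌋ synthetic points by convex interpolation toward one
of its k=5 nearest minority neighbours, and the majority class is
down-sampled without replacement to round(perc.under/100 × n_synthetic).
Rebalancing, z-scores, selection and preprocessors are fitted on the
training cohort only; every fitted transform records its cohort tag and any
attempt to fit on validation/test raises (the leakage guard is tested, not
advisory).

Feature selection is RFE (L2-logistic base model, one elimination per step,
`rfe_keep` default 30) followed by an L1-logistic path with 10-fold CV on α
at minimal CV deviance. Exactly duplicated columns are collapsed to their
first occurrence before RFE, since clones split the linear weight and would
otherwise survive together. An all-zero support triggers a documented
fallback: the path is walked toward weaker penalties (continuing past the
grid edge) to the first non-empty support.

The grid crosses Box-Cox (with a per-feature min+ε positivity shift),
MaxAbs, quantile and Yeo-Johnson preprocessors with random forest
(200 trees), logistic regression, QDA (reg_param 1e-3 for covariance
stability), SVM (probability outputs) and decision tree, all seeded, no
inner hyperparameter search. Ranking is by validation AUC, ties broken by
validation accuracy then fixed grid order.

Evaluation: AUC by all-pairs concordance with ties at ½; its CI and the
paired two-model test use the DeLong placement-value variance (degenerate
zero variance → z=0, p=1, flagged by convention). Proportion metrics carry
Wilson intervals (the CI method for such tables is rarely stated; Wilson is
the default here). The operating threshold is Youden's J on the training
cohort — a declared substitute for an externally chosen cut-point, not a
reconstruction of one. DeLong p-values are reported raw, without
multiple-testing correction. Shapley attribution is exact interventional
enumeration over all 2^d coalitions against a background sample, refusing
d > 15; efficiency (Σφ = f(x) − baseline) holds by construction and is
asserted numerically. The baseline-table summary routes continuous
variables by a Lilliefors-form Kolmogorov-Smirnov normality gate at 0.05
(moments are estimated from the sample, so the parametric KS null would be
anticonservative); 2×2 chi-square statistics are exported both with and
without continuity correction.

## Orchestration and problem sizes

The pipeline caches the MSI feature table keyed by a hash of every upstream
config key: re-running an unchanged config resumes from it, and editing any
upstream key invalidates exactly the downstream stages that consume it. The
manifest records per-stage checksums and timestamps; deterministic stages
reproduce identical checksums.

Default experiment sizes (355 cases, ~30³-voxel VOIs at 1 mm, 100
supervoxels/lesion, mixtures for k = 1..6) run in a few minutes on one CPU;
the examples use 40–80-case cohorts for the same reason. These sizes are the
package's chosen desk-scale study conditions, at which the elbow selection,
the direction of the grade effect, and validation AUC > 0.75 are stable
across seeds.

## Known limitations

* Supervoxel phenotypes are intensity-only; texture or multi-channel
  phenotypes (perfusion, PET) are out of scope.
* Border counts are unweighted voxel-pair counts; anisotropy-aware surface
  weighting is not implemented.
* The logistic fallback under perfect separation reports penalized
  coefficients without confidence intervals.
* The generator does not simulate scanner physics, dose, reconstruction
  kernels, multi-center effects or longitudinal change; conclusions about
  real-cohort performance require real cohorts.
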