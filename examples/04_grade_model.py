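"""Train and evaluate a grade-prediction MSI model on a reduced cohort.

The harness rebalances the training cohort with SMOTE, standardizes with
training statistics, selects features by RFE + L1-logistic CV, crosses four
preprocessors with five classifiers, picks the best pair on validation AUC
and evaluates on the held-out test cohort at the training Youden cut-point.
"""

from habitatmsi.pipeline import run_msi_experiment
from habitatmsi.synthetic import CohortRecipe

recipe = CohortRecipe(n_train=48, n_val=16, n_test=16, seed=3)
res = run_msi_experiment(recipe, seed=3)

best = res["grid"].best
print(f"subregions selected: k = {res['subregion_model'].k}")
print(f"features selected ({len(res['selection'].selected)}):",
      ", ".join(res["selection"].selected[:6]), "...")
print(f"best candidate: {best.preprocessor_name} + {best.classifier_name}")
print(f"operating threshold (training Youden): {res['threshold']:.3f}\n")
for cohort in ("train", "val", "test"):
    r = res["reports"][cohort]
    print(
        f"{cohort:>5}: AUC {r.auc:.3f} ({r.auc_ci[0]:.3f}-{r.auc_ci[1]:.3f})  "
        f"sens {r.sensitivity:.2f}  spec {r.specificity:.2f}  brier {r.brier:.3f}"
    )
print(
    "\nAUC near 1 on this synthetic cohort reflects the strong grade effect\n"
    "encoded in the generator (dense fraction 0.62 vs 0.18); the harness and\n"
    "its leakage guards, not the difficulty of the task, are what is exercised."
)
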