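"""Grade-prediction modeling: rebalancing, selection and the model grid.

All fitted transforms record the cohort tag they were fitted on; fitting or
rebalancing anything but the training cohort is a hard error, which is the
package's leakage guard. The model grid crosses four preprocessors (Box-Cox,
MaxAbs, quantile, Yeo-Johnson) with five classifiers (random forest,
logistic regression, QDA, SVM, decision tree); candidates are ranked by
validation-cohort AUC, with ties broken by validation accuracy and then by
fixed grid order.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import MaxAbsScaler, PowerTransformer, QuantileTransformer
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .evaluation import roc_auc

__all__ = [
    "ResampleSpec",
    "FeatureSelectionSpec",
    "ModelGridSpec",
    "CohortTagError",
    "smote_resample",
    "zscore_fit_apply",
    "select_features",
    "logistic_assoc",
    "grid_train",
]


class CohortTagError(RuntimeError):
    """A training-only operation was invoked on a non-training cohort."""


@contextmanager
def _quiet_sklearn():
    # scikit-learn 1.9 deprecation churn (penalty= / SVC probability=);
    # semantics are unchanged on the pinned version range
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        yield


@dataclass(frozen=True)
class ResampleSpec:
    """SMOTE-with-undersampling parameters, perc.over/perc.under convention.

    ``perc_over`` percent of the minority count is generated as synthetic
    minority cases (floor(perc_over/100) per real case); the majority class
    is then down-sampled to ``perc_under`` percent of the synthetic count.
    """

    perc_over: float = 200.0
    perc_under: float = 155.0
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.perc_over < 0 or self.perc_under < 0:
            raise ValueError("percentages must be non-negative")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def smote_resample(
    features: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    spec: ResampleSpec = ResampleSpec(),
    cohort_tag: str = "train",
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class by convex interpolation, then undersample.

    Each minority case spawns ``floor(perc_over/100)`` synthetic points, each
    lying on the segment toward a uniformly chosen one of its ``k_neighbors``
    nearest minority neighbours. The majority class is down-sampled without
    replacement to ``round(perc_under/100 × n_synthetic)`` (capped at its own
    size). Only ever applicable to the training cohort.
    """
    if cohort_tag != "train":
        raise CohortTagError(f"SMOTE may only touch the training cohort, got {cohort_tag!r}")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote_resample requires binary labels")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    X_min, X_maj = X[y == minority], X[y == majority]
    if len(X_min) < spec.k_neighbors + 1:
        raise ValueError(
            f"minority class has {len(X_min)} cases; needs >= k_neighbors+1 = "
            f"{spec.k_neighbors + 1}"
        )

    rng = np.random.default_rng(spec.seed)
    n_per_case = int(spec.perc_over // 100)
    nn = NearestNeighbors(n_neighbors=spec.k_neighbors + 1).fit(X_min)
    _, idx = nn.kneighbors(X_min)
    synthetic = []
    for i in range(len(X_min)):
        neigh = idx[i, 1:]  # drop self
        for _ in range(n_per_case):
            j = neigh[rng.integers(len(neigh))]
            lam = rng.uniform()
            synthetic.append(X_min[i] + lam * (X_min[j] - X_min[i]))
    X_syn = np.asarray(synthetic) if synthetic else np.empty((0, X.shape[1]))

    n_keep = min(int(round(spec.perc_under / 100.0 * len(X_syn))), len(X_maj))
    keep = rng.choice(len(X_maj), size=n_keep, replace=False)
    X_out = np.vstack([X_min, X_syn, X_maj[keep]])
    y_out = np.concatenate(
        [
            np.full(len(X_min) + len(X_syn), minority),
            np.full(n_keep, majority),
        ]
    )
    return X_out, y_out


@dataclass
class ZScoreParams:
    mean: np.ndarray
    sd: np.ndarray
    constant_columns: np.ndarray
    fitted_on: str = "train"


def zscore_fit_apply(
    train_features: pd.DataFrame | np.ndarray,
    *other_features: pd.DataFrame | np.ndarray,
    cohort_tag: str = "train",
) -> tuple[list[np.ndarray], ZScoreParams]:
    """Standardize with training-cohort means/SDs applied to every cohort.

    Zero-variance training columns are flagged and passed through centered
    (divided by 1 instead of 0).
    """
    if cohort_tag != "train":
        raise CohortTagError("z-score parameters must be fitted on the training cohort")
    Xt = np.asarray(train_features, dtype=float)
    mean = Xt.mean(axis=0)
    sd = Xt.std(axis=0, ddof=0)
    const = sd == 0
    sd_safe = np.where(const, 1.0, sd)
    params = ZScoreParams(mean=mean, sd=sd_safe, constant_columns=const)
    out = [(np.asarray(X, dtype=float) - mean) / sd_safe for X in (Xt, *other_features)]
    return out, params


@dataclass(frozen=True)
class FeatureSelectionSpec:
    rfe_keep: int = 30
    lasso_alpha_grid: tuple[float, ...] = tuple(np.logspace(-3, 2, 30))
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rfe_keep < 1:
            raise ValueError("rfe_keep must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class SelectionResult:
    selected: list[str]
    coefficients: dict[str, float]
    alpha: float
    rfe_ranking: dict[str, int]
    empty_fallback: bool = False
    fitted_on: str = "train"


def select_features(
    train_features: pd.DataFrame,
    labels: np.ndarray,
    spec: FeatureSelectionSpec = FeatureSelectionSpec(),
    cohort_tag: str = "train",
) -> SelectionResult:
    """RFE to ``rfe_keep`` features, then an L1-logistic path with CV on α.

    RFE uses an L2-logistic base model eliminating one feature per step. The
    LASSO stage picks the α with minimal cross-validated deviance; if every
    coefficient is shrunk to zero there, the smallest α that keeps a
    non-empty support is used instead and the result is flagged.
    """
    if cohort_tag != "train":
        raise CohortTagError("feature selection must run on the training cohort")
    # exactly duplicated columns are collapsed to their first occurrence:
    # RFE splits weight evenly across clones and would otherwise keep both
    dedup = train_features.T.drop_duplicates().T
    X = dedup.to_numpy(dtype=float)
    names = list(dedup.columns)
    y = np.asarray(labels)

    keep = min(spec.rfe_keep, len(names))
    rfe = RFE(
        LogisticRegression(max_iter=2000),
        n_features_to_select=keep,
        step=1,
    ).fit(X, y)
    kept_idx = np.flatnonzero(rfe.support_)
    kept_names = [names[i] for i in kept_idx]
    ranking = {n: int(r) for n, r in zip(names, rfe.ranking_)}

    Cs = sorted(1.0 / np.asarray(spec.lasso_alpha_grid, dtype=float))
    cv = LogisticRegressionCV(
        Cs=Cs,
        cv=spec.cv_folds,
        l1_ratios=(1.0,),
        solver="liblinear",
        scoring="neg_log_loss",
        random_state=spec.seed,
        max_iter=5000,
        use_legacy_attributes=False,
    ).fit(X[:, kept_idx], y)
    coefs = cv.coef_.ravel()
    alpha = 1.0 / float(np.atleast_1d(cv.C_)[0])
    fallback = False
    if not np.any(coefs != 0):
        # walk the penalty path downward (weaker and weaker shrinkage) to the
        # first α whose support is non-empty, continuing past the grid edge
        # if the whole grid over-shrinks
        fallback = True
        path = list(Cs) + [max(Cs) * 10.0**i for i in range(1, 13)]
        for C in path:
            lr = LogisticRegression(
                l1_ratio=1.0, C=C, solver="liblinear", max_iter=5000
            ).fit(X[:, kept_idx], y)
            if np.any(lr.coef_ != 0):
                coefs = lr.coef_.ravel()
                alpha = 1.0 / C
                break
    nz = np.flatnonzero(coefs)
    return SelectionResult(
        selected=[kept_names[i] for i in nz],
        coefficients={kept_names[i]: float(coefs[i]) for i in nz},
        alpha=alpha,
        rfe_ranking=ranking,
        empty_fallback=fallback,
    )


def logistic_assoc(
    table: pd.DataFrame,
    outcome: str,
    variables: list[str],
    mode: str = "univariate",
    alpha_enter: float = 0.05,
) -> pd.DataFrame:
    """Univariate or multivariate logistic association with ORs and Wald CIs.

    ``multivariate`` refits jointly on the variables whose univariate p-value
    is below ``alpha_enter``. Perfect separation is flagged and handled with
    an L2-penalized fallback fit (no CI reported for that row).
    """
    y = np.asarray(table[outcome], dtype=float)

    def _fit(cols: list[str]) -> pd.DataFrame:
        X = sm.add_constant(table[cols].to_numpy(dtype=float), has_constant="add")
        rows = []
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            separated = not np.all(np.isfinite(res.bse))
        except Exception:
            res, separated = None, True
        if res is not None and not separated:
            ci = res.conf_int()
            for i, c in enumerate(cols, start=1):
                rows.append(
                    {
                        "variable": c,
                        "coefficient": float(res.params[i]),
                        "or": float(np.exp(res.params[i])),
                        "ci_low": float(np.exp(ci[i, 0])),
                        "ci_high": float(np.exp(ci[i, 1])),
                        "p_value": float(res.pvalues[i]),
                        "separation_flag": False,
                    }
                )
        else:
            pen = LogisticRegression(C=1.0, max_iter=2000).fit(
                table[cols].to_numpy(dtype=float), y
            )
            for i, c in enumerate(cols):
                rows.append(
                    {
                        "variable": c,
                        "coefficient": float(pen.coef_[0, i]),
                        "or": float(np.exp(pen.coef_[0, i])),
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "p_value": np.nan,
                        "separation_flag": True,
                    }
                )
        return pd.DataFrame(rows)

    uni = pd.concat([_fit([v]) for v in variables], ignore_index=True)
    if mode == "univariate":
        return uni
    if mode != "multivariate":
        raise ValueError("mode must be 'univariate' or 'multivariate'")
    sig = [
        v
        for v in variables
        if bool(
            uni.loc[uni["variable"] == v, "p_value"].notna().all()
            and (uni.loc[uni["variable"] == v, "p_value"] < alpha_enter).all()
        )
    ]
    if not sig:
        return uni.iloc[0:0]
    return _fit(sig)


PREPROCESSOR_ORDER = ("box_cox", "maxabs", "quantile", "yeo_johnson")
CLASSIFIER_ORDER = ("random_forest", "logistic", "qda", "svm", "decision_tree")


@dataclass(frozen=True)
class ModelGridSpec:
    preprocessors: tuple[str, ...] = PREPROCESSOR_ORDER
    classifiers: tuple[str, ...] = CLASSIFIER_ORDER
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.preprocessors or not self.classifiers:
            raise ValueError("grid must be non-empty × non-empty")
        bad = set(self.preprocessors) - set(PREPROCESSOR_ORDER)
        bad |= set(self.classifiers) - set(CLASSIFIER_ORDER)
        if bad:
            raise ValueError(f"unknown grid entries: {sorted(bad)}")


class _BoxCoxShift:
    """Box-Cox preprocessor with a per-feature min+ε shift to enforce the
    transform's positivity requirement."""

    def __init__(self):
        self._pt = PowerTransformer(method="box-cox", standardize=True)
        self._shift = None

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self._shift = X.min(axis=0) - 1e-6
        self._pt.fit(X - self._shift + 1e-6)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        shifted = np.maximum(X - self._shift + 1e-6, 1e-9)
        return self._pt.transform(shifted)


def _make_preprocessor(name: str, seed: int, n_train: int):
    if name == "box_cox":
        return _BoxCoxShift()
    if name == "maxabs":
        return MaxAbsScaler()
    if name == "quantile":
        return QuantileTransformer(
            n_quantiles=min(n_train, 1000), random_state=seed
        )
    if name == "yeo_johnson":
        return PowerTransformer(method="yeo-johnson", standardize=True)
    raise ValueError(name)


def _make_classifier(name: str, seed: int):
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if name == "logistic":
        return LogisticRegression(max_iter=2000)
    if name == "qda":
        return QuadraticDiscriminantAnalysis(reg_param=1e-3)
    if name == "svm":
        return SVC(probability=True, random_state=seed)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(name)


@dataclass
class FittedCandidate:
    preprocessor_name: str
    classifier_name: str
    preprocessor: object
    classifier: object
    val_auc: float
    val_accuracy: float

    def predict_proba(self, X) -> np.ndarray:
        Z = self.preprocessor.transform(np.asarray(X, dtype=float))
        return self.classifier.predict_proba(Z)[:, 1]


@dataclass
class GridResult:
    candidates: list[FittedCandidate]
    ranking: pd.DataFrame
    best: FittedCandidate


def grid_train(
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    grid: ModelGridSpec = ModelGridSpec(),
) -> GridResult:
    """Fit every preprocessor×classifier pair on train; rank on validation AUC.

    Preprocessors are fitted on the training features only. The validation
    cohort is used solely to select the best candidate.
    """
    Xt, yt = (np.asarray(a) for a in train)
    Xv, yv = (np.asarray(a) for a in val)
    if len(np.unique(yv)) < 2:
        raise ValueError("validation cohort has a single class; AUC undefined")

    candidates = []
    for p_name in grid.preprocessors:
        for c_name in grid.classifiers:
            prep = _make_preprocessor(p_name, grid.seed, len(Xt))
            prep.fit(Xt.astype(float))
            Zt = prep.transform(Xt.astype(float))
            with _quiet_sklearn():
                clf = _make_classifier(c_name, grid.seed)
                clf.fit(Zt, yt)
            Zv = prep.transform(Xv.astype(float))
            pv = clf.predict_proba(Zv)[:, 1]
            auc, _ = roc_auc(pv, yv)
            acc = float(np.mean((pv >= 0.5).astype(int) == yv))
            candidates.append(
                FittedCandidate(p_name, c_name, prep, clf, auc, acc)
            )

    order = sorted(
        range(len(candidates)),
        key=lambda i: (-candidates[i].val_auc, -candidates[i].val_accuracy, i),
    )
    ranking = pd.DataFrame(
        {
            "preprocessor": [candidates[i].preprocessor_name for i in order],
            "classifier": [candidates[i].classifier_name for i in order],
            "val_auc": [candidates[i].val_auc for i in order],
            "val_accuracy": [candidates[i].val_accuracy for i in order],
        }
    )
    return GridResult(candidates=candidates, ranking=ranking, best=candidates[order[0]])
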