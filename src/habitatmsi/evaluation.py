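"""Model evaluation statistics.

AUC uses the rank/concordance (Mann-Whitney) formulation with ties counted
one half; its confidence interval and the paired-model comparison both use
the DeLong placement-value variance. Operating-point metrics (sensitivity,
specificity, PPV, NPV, accuracy) carry Wilson score intervals. Decision-curve
net benefit, quantile-binned calibration with the Brier score, exact
interventional Shapley attribution (full subset enumeration, d ≤ 15),
diameter-stratified subgroup evaluation and the proportion-estimation sample
size formula complete the harness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "roc_auc",
    "delong_test",
    "calibration_brier",
    "decision_curve",
    "shapley_attribution",
    "subgroup_eval",
    "required_sample_size",
    "SampleSizeSpec",
    "cohort_summary",
    "evaluate_model",
    "youden_threshold",
    "EvalReport",
]


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong
# ---------------------------------------------------------------------------

def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    # V10_i = fraction of negatives below pos_i (ties count 1/2)
    v10 = np.empty(m)
    v01 = np.empty(n)
    for i, s in enumerate(pos):
        v10[i] = (np.sum(neg < s) + 0.5 * np.sum(neg == s)) / n
    for j, s in enumerate(neg):
        v01[j] = (np.sum(pos > s) + 0.5 * np.sum(pos == s)) / m
    return v10, v01


def roc_auc(scores, labels) -> tuple[float, tuple[float, float]]:
    """AUC by all-pairs concordance (ties = 1/2) with a DeLong-variance CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    v10, v01 = _placements(scores, labels)
    auc = float(v10.mean())
    m, n = len(v10), len(v01)
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    half = 1.959963984540054 * math.sqrt(max(var, 0.0))
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Two-sided DeLong test for two correlated (same-case) ROC curves.

    Returns (z, p). A degenerate zero variance (e.g. identical score
    vectors) yields z = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired scores must align with labels")
    va10, va01 = _placements(scores_a, labels)
    vb10, vb01 = _placements(scores_b, labels)
    auc_a, auc_b = va10.mean(), vb10.mean()
    m, n = len(va10), len(va01)

    s10 = np.cov(np.vstack([va10, vb10]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        return 0.0, 1.0
    z = float((auc_a - auc_b) / math.sqrt(var_diff))
    p = float(2 * stats.norm.sf(abs(z)))
    return z, p


# ---------------------------------------------------------------------------
# Calibration / decision curves
# ---------------------------------------------------------------------------

def calibration_brier(probs, labels, n_bins: int = 10) -> tuple[pd.DataFrame, float]:
    """Quantile-binned calibration table and the Brier score."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(float)
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    brier = float(np.mean((probs - labels) ** 2))
    edges = np.quantile(probs, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    which = np.searchsorted(edges, probs, side="right") - 1
    rows = []
    for b in range(n_bins):
        sel = which == b
        if not sel.any():
            continue
        rows.append(
            {
                "bin": b,
                "n": int(sel.sum()),
                "mean_predicted": float(probs[sel].mean()),
                "observed_rate": float(labels[sel].mean()),
            }
        )
    return pd.DataFrame(rows), brier


def decision_curve(probs, labels, thresholds) -> pd.DataFrame:
    """Net benefit per threshold pt, with treat-all and treat-none references.

    net_benefit = TP/n − FP/n · pt/(1−pt); treat-none ≡ 0;
    treat-all = prevalence − (1 − prevalence) · pt/(1−pt).
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds <= 0) or np.any(thresholds >= 1):
        raise ValueError("thresholds must lie in (0, 1)")
    n = len(labels)
    prev = labels.mean()
    rows = []
    for pt in thresholds:
        w = pt / (1 - pt)
        pred = probs >= pt
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        rows.append(
            {
                "threshold": float(pt),
                "net_benefit": tp / n - fp / n * w,
                "treat_all": prev - (1 - prev) * w,
                "treat_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Exact Shapley attribution
# ---------------------------------------------------------------------------

def shapley_attribution(
    predict, case_features, background_features
) -> tuple[np.ndarray, float]:
    """Exact interventional Shapley values for one case.

    ``predict`` maps an (n, d) array to scalar outputs. The value of a
    coalition S is the mean prediction over background rows with the case's
    values substituted on S; Shapley weights average marginal contributions
    over all 2^d coalitions. Requires d ≤ 15 (exact enumeration; no sampling
    approximation is offered). The efficiency identity
    Σ φ_i = f(case) − mean f(background) holds by construction.

    Returns (attributions, base_value).
    """
    x = np.asarray(case_features, dtype=float).ravel()
    bg = np.atleast_2d(np.asarray(background_features, dtype=float))
    d = x.size
    if d > 15:
        raise ValueError("exact Shapley enumeration supports at most 15 features")
    if bg.shape[1] != d:
        raise ValueError("background feature dimension mismatch")

    n_bg = bg.shape[0]
    n_sets = 1 << d
    # v(S): mean prediction over background rows with x substituted on S
    batch = np.empty((n_sets * n_bg, d))
    for s in range(n_sets):
        block = bg.copy()
        for i in range(d):
            if s >> i & 1:
                block[:, i] = x[i]
        batch[s * n_bg : (s + 1) * n_bg] = block
    preds = np.asarray(predict(batch), dtype=float).reshape(n_sets, n_bg)
    v = preds.mean(axis=1)

    fact = [math.factorial(i) for i in range(d + 1)]
    phi = np.zeros(d)
    for s in range(n_sets):
        size = bin(s).count("1")
        for i in range(d):
            if s >> i & 1:
                continue
            w = fact[size] * fact[d - size - 1] / fact[d]
            phi[i] += w * (v[s | (1 << i)] - v[s])
    return phi, float(v[0])


# ---------------------------------------------------------------------------
# Operating-point evaluation and subgroups
# ---------------------------------------------------------------------------

def _wilson(k: int, n: int) -> tuple[float, float]:
    if n == 0:
        return (np.nan, np.nan)
    lo, hi = stats.binomtest(k, n).proportion_ci(confidence_level=0.95, method="wilson")
    return float(lo), float(hi)


@dataclass
class EvalReport:
    """Operating-point and ranking metrics for one cohort."""

    cohort: str
    n: int
    auc: float
    auc_ci: tuple[float, float]
    threshold: float
    accuracy: float
    accuracy_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    ppv: float
    ppv_ci: tuple[float, float]
    npv: float
    npv_ci: tuple[float, float]
    brier: float
    single_class: bool = False


def youden_threshold(probs, labels) -> float:
    """Probability cut-point maximizing Youden's J = sens + spec − 1."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    cand = np.unique(probs)
    best_t, best_j = 0.5, -np.inf
    for t in cand:
        pred = probs >= t
        sens = np.mean(pred[labels == 1]) if (labels == 1).any() else 0.0
        spec = np.mean(~pred[labels == 0]) if (labels == 0).any() else 0.0
        j = sens + spec - 1
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


def evaluate_model(probs, labels, threshold: float, cohort: str = "") -> EvalReport:
    """Full metric panel at a fixed probability cut-point."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    single = len(np.unique(labels)) < 2
    if single:
        auc, ci = np.nan, (np.nan, np.nan)
    else:
        auc, ci = roc_auc(probs, labels)
    pred = (probs >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    n = len(labels)

    def rate(num, den):
        return num / den if den else np.nan

    _, brier = calibration_brier(probs, labels)
    return EvalReport(
        cohort=cohort,
        n=n,
        auc=auc,
        auc_ci=ci,
        threshold=float(threshold),
        accuracy=rate(tp + tn, n),
        accuracy_ci=_wilson(tp + tn, n),
        sensitivity=rate(tp, tp + fn),
        sensitivity_ci=_wilson(tp, tp + fn),
        specificity=rate(tn, tn + fp),
        specificity_ci=_wilson(tn, tn + fp),
        ppv=rate(tp, tp + fp),
        ppv_ci=_wilson(tp, tp + fp),
        npv=rate(tn, tn + fn),
        npv_ci=_wilson(tn, tn + fn),
        brier=brier,
        single_class=single,
    )


DIAMETER_STRATA = (
    ("<=20mm", lambda d: d <= 20),
    (">20-30mm", lambda d: (d > 20) & (d <= 30)),
    (">30mm", lambda d: d > 30),
)


def subgroup_eval(
    probs, labels, diameter_mm, threshold: float = 0.5
) -> dict[str, EvalReport]:
    """Diameter-stratified evaluation: ≤20 mm, >20–≤30 mm, >30 mm.

    Strata partition the cohort exactly; an empty stratum is omitted and a
    single-class stratum is flagged on its report, never raised.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    d = np.asarray(diameter_mm, dtype=float)
    out = {}
    for name, pred in DIAMETER_STRATA:
        sel = pred(d)
        if not sel.any():
            continue
        out[name] = evaluate_model(probs[sel], labels[sel], threshold, cohort=name)
    return out


# ---------------------------------------------------------------------------
# Sample size and cohort summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSizeSpec:
    """Proportion-estimation sample size: n = ceil(Z² P(1−P) / Δ²)."""

    alpha: float = 0.05
    delta: float = 0.08

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.delta <= 0:
            raise ValueError("delta must be positive")

    @property
    def z(self) -> float:
        return float(stats.norm.ppf(1 - self.alpha / 2))


def required_sample_size(
    proportions, spec: SampleSizeSpec = SampleSizeSpec()
) -> tuple[list[int], int]:
    """Per-proportion n and their total, e.g. for a sensitivity/specificity
    pair. P in {0, 1} yields a degenerate n = 0."""
    z2 = spec.z**2
    ns = []
    for p in np.atleast_1d(proportions):
        if not 0 <= p <= 1:
            raise ValueError("proportions must lie in [0, 1]")
        ns.append(int(math.ceil(z2 * p * (1 - p) / spec.delta**2)))
    return ns, int(sum(ns))


def cohort_summary(
    table: pd.DataFrame,
    group: str,
    variables: list[str],
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Baseline-table-style per-variable summary with the matching test.

    Continuous variables are routed by a Kolmogorov-Smirnov normality gate
    (Lilliefors form, since moments are estimated): normal → mean ± SD with
    the two-sample t-test; skewed → median [Q1, Q3] with the Mann-Whitney U
    test. Categorical variables get n (%) with the chi-square test, reported
    both without and with continuity correction for 2×2 tables.
    """
    from statsmodels.stats.diagnostic import lilliefors

    groups = table[group].unique()
    if len(groups) != 2:
        raise ValueError("cohort_summary compares exactly two groups")
    g0 = table[table[group] == groups[0]]
    g1 = table[table[group] == groups[1]]

    rows = []
    for var in variables:
        col = table[var]
        if pd.api.types.is_numeric_dtype(col):
            try:
                _, p_norm = lilliefors(col.dropna().to_numpy(), dist="norm")
            except Exception:
                p_norm = 0.0
            a, b = g0[var].dropna(), g1[var].dropna()
            if p_norm >= normality_alpha:
                stat, p = stats.ttest_ind(a, b, equal_var=True)
                summ0 = f"{a.mean():.2f} ± {a.std():.2f}"
                summ1 = f"{b.mean():.2f} ± {b.std():.2f}"
                test = "t-test"
            else:
                stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                summ0 = f"{a.median():.2f} [{a.quantile(.25):.2f}, {a.quantile(.75):.2f}]"
                summ1 = f"{b.median():.2f} [{b.quantile(.25):.2f}, {b.quantile(.75):.2f}]"
                test = "mann-whitney"
            rows.append(
                {
                    "variable": var,
                    "type": "continuous",
                    "test": test,
                    "summary_group0": summ0,
                    "summary_group1": summ1,
                    "statistic": float(stat),
                    "p_value": float(p),
                }
            )
        else:
            ct = pd.crosstab(table[var], table[group])
            chi2, p, _, _ = stats.chi2_contingency(ct.to_numpy(), correction=False)
            stat_corr, p_corr = np.nan, np.nan
            if ct.shape == (2, 2):
                stat_corr, p_corr, _, _ = stats.chi2_contingency(
                    ct.to_numpy(), correction=True
                )
            levels = ", ".join(
                f"{lv}: {int(ct.loc[lv, groups[0]])}/{int(ct.loc[lv, groups[1]])}"
                for lv in ct.index
            )
            rows.append(
                {
                    "variable": var,
                    "type": "categorical",
                    "test": "chi-square",
                    "summary_group0": levels,
                    "summary_group1": "",
                    "statistic": float(chi2),
                    "p_value": float(p),
                    "statistic_corrected": float(stat_corr) if ct.shape == (2, 2) else np.nan,
                    "p_value_corrected": float(p_corr) if ct.shape == (2, 2) else np.nan,
                }
            )
    return pd.DataFrame(rows)
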