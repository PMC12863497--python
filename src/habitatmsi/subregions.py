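"""Two-stage habitat discovery.

Stage 1 (per lesion): SLIC supervoxel oversegmentation of the
window-normalized VOI, restricted to the lesion mask, yielding a phenotype
table (mean normalized intensity and size per supervoxel).

Stage 2 (cohort level): a 1-D Gaussian mixture over the pooled training
supervoxel phenotypes, fitted for a range of candidate component counts; the
subregion count is chosen by the elbow of the hard-assignment
sum-of-squared-errors curve (maximal second difference). The fitted model is
then applied unchanged to held-out lesions, so subregion semantics are
consistent across cohorts.

Canonical label semantics: subregion 1 has the highest mean attenuation,
subregion 2 the lowest, and subregion 3..k the remaining components in
descending attenuation — matching the convention that subregion 1 is the
dense, sub-solid habitat and subregion 2 the air-like habitat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.segmentation import slic
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .volume import CTVolume, EmptyMaskError, LesionMask

__all__ = [
    "SupervoxelSpec",
    "SupervoxelMap",
    "SubregionModel",
    "SubregionLabelMap",
    "compute_supervoxels",
    "fit_subregion_model",
    "select_k_elbow",
    "assign_subregions",
    "subregion_stats",
]


class InvalidCurveError(ValueError):
    """SSE curve increases beyond tolerance; no elbow is defined."""


class DegenerateFitError(ValueError):
    """Too few phenotype rows for the requested mixture sizes."""


@dataclass(frozen=True)
class SupervoxelSpec:
    """SLIC parameters; compactness is on the unit intensity scale."""

    n_segments: int = 100
    compactness: float = 0.1
    enforce_connectivity: bool = True

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.compactness <= 0:
            raise ValueError("compactness must be positive")


@dataclass
class SupervoxelMap:
    """Supervoxel label grid (0 outside mask, 1..S inside) + phenotype table."""

    labels: np.ndarray
    phenotypes: pd.DataFrame  # columns: supervoxel, mean_intensity, n_voxels

    @property
    def n_supervoxels(self) -> int:
        return len(self.phenotypes)


def compute_supervoxels(
    voi: CTVolume, mask: LesionMask, spec: SupervoxelSpec = SupervoxelSpec()
) -> SupervoxelMap:
    """Oversegment the masked VOI into SLIC supervoxels.

    Supervoxels partition the mask exactly: every in-mask voxel belongs to
    exactly one supervoxel and no supervoxel extends outside the mask.
    """
    if voi.value_domain != "unit":
        raise ValueError("compute_supervoxels expects a window-normalized VOI")
    mask.check_aligned(voi)
    if mask.n_foreground == 0:
        raise EmptyMaskError("cannot compute supervoxels on an empty mask")

    img = np.ascontiguousarray(voi.voxels, dtype=np.float64)
    labels = slic(
        img,
        n_segments=spec.n_segments,
        compactness=spec.compactness,
        mask=mask.voxels,
        enforce_connectivity=spec.enforce_connectivity,
        channel_axis=None,
        start_label=1,
    )
    labels = np.where(mask.voxels, labels, 0)
    # SLIC label ids may be sparse; relabel to a dense 1..S range.
    present = np.unique(labels[labels > 0])
    remap = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    remap[present] = np.arange(1, len(present) + 1)
    labels = remap[labels]

    inmask = labels[mask.voxels]
    vals = img[mask.voxels]
    sums = np.bincount(inmask, weights=vals, minlength=len(present) + 1)
    counts = np.bincount(inmask, minlength=len(present) + 1)
    ids = np.arange(1, len(present) + 1)
    pheno = pd.DataFrame(
        {
            "supervoxel": ids,
            "mean_intensity": sums[1:] / counts[1:],
            "n_voxels": counts[1:].astype(int),
        }
    )
    return SupervoxelMap(labels=labels, phenotypes=pheno)


@dataclass
class SubregionModel:
    """Cohort-level mixture over supervoxel phenotypes.

    ``label_order`` maps raw mixture-component indices (0-based) to canonical
    subregion labels (1-based): component ``c`` paints subregion
    ``label_order[c]``.
    """

    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    label_order: np.ndarray
    sse_curve: dict[int, float]
    fit_seed: int
    sse_monotonized: bool = False
    _gmms: dict[int, GaussianMixture] = field(default_factory=dict, repr=False)

    @property
    def fitted(self) -> bool:
        return self.k >= 1 and len(self.means) == self.k

    def canonical_means(self) -> np.ndarray:
        """Component means indexed by canonical subregion label 1..k."""
        out = np.empty(self.k)
        out[self.label_order - 1] = self.means
        return out


def _canonical_order(means: np.ndarray) -> np.ndarray:
    """Canonical labels: 1 = highest mean, 2 = lowest, 3.. = rest descending."""
    k = len(means)
    order = np.empty(k, dtype=int)
    desc = np.argsort(-means, kind="stable")
    if k == 1:
        order[desc[0]] = 1
        return order
    order[desc[0]] = 1
    order[desc[-1]] = 2
    for rank, comp in enumerate(desc[1:-1], start=3):
        order[comp] = rank
    return order


def _hard_sse(x: np.ndarray, gmm: GaussianMixture) -> float:
    """Within-cluster SSE under hard maximum-posterior assignment."""
    assign = gmm.predict(x)
    sse = 0.0
    for c in np.unique(assign):
        pts = x[assign == c, 0]
        sse += float(((pts - pts.mean()) ** 2).sum())
    return sse


def fit_subregion_model(
    phenotypes: pd.DataFrame | np.ndarray,
    k_candidates=range(1, 7),
    seed: int = 0,
) -> SubregionModel:
    """Fit mixtures over pooled training phenotypes and pick k by the elbow.

    The SSE used for the elbow is the within-cluster sum of squared phenotype
    deviations under hard maximum-posterior assignment (the mixture
    log-likelihood itself is monotone in k and has no natural elbow scale).
    EM local optima can make the raw curve tick upward at some k; a running
    minimum is applied before elbow selection and the correction is flagged
    on the model.
    """
    if isinstance(phenotypes, pd.DataFrame):
        x = phenotypes["mean_intensity"].to_numpy(dtype=float)
    else:
        x = np.asarray(phenotypes, dtype=float).ravel()
    ks = sorted(set(int(k) for k in k_candidates))
    if not ks:
        raise ValueError("k_candidates must be non-empty")
    if len(x) < max(ks):
        raise DegenerateFitError(
            f"{len(x)} phenotype rows cannot support k up to {max(ks)}"
        )
    x = x.reshape(-1, 1)

    gmms: dict[int, GaussianMixture] = {}
    sse_raw: dict[int, float] = {}
    for k in ks:
        with warnings.catch_warnings():
            # near-duplicate restarts at large k can stop on max_iter without
            # affecting the hard-assignment SSE at the precision used here
            warnings.simplefilter("ignore", ConvergenceWarning)
            gmm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                n_init=10,
                tol=1e-6,
                reg_covar=1e-9,
                max_iter=500,
                random_state=seed,
            ).fit(x)
        gmms[k] = gmm
        sse_raw[k] = _hard_sse(x, gmm)

    sse_vals = np.minimum.accumulate([sse_raw[k] for k in ks])
    monotonized = any(
        abs(sse_vals[i] - sse_raw[k]) > 0 for i, k in enumerate(ks)
    )
    sse_curve = dict(zip(ks, (float(v) for v in sse_vals)))
    k_sel = select_k_elbow(sse_curve) if len(ks) >= 3 else ks[0]

    best = gmms[k_sel]
    means = best.means_.ravel()
    return SubregionModel(
        k=k_sel,
        weights=best.weights_.copy(),
        means=means.copy(),
        variances=best.covariances_.reshape(-1).copy(),
        label_order=_canonical_order(means),
        sse_curve=sse_curve,
        fit_seed=seed,
        sse_monotonized=monotonized,
        _gmms=gmms,
    )


def select_k_elbow(sse_curve) -> int:
    """Elbow of an SSE-vs-k curve: the interior k of maximal curvature.

    Curvature is measured as the second difference of log-SSE. The log scale
    makes the criterion invariant to the overall SSE magnitude, so an elbow
    separating well-resolved clusters is found even when cluster separations
    (and hence the successive SSE drops) differ by orders of magnitude —
    absolute second differences would always favour the first large drop.

    Requires at least 3 points and a non-increasing curve (tolerance 1e-9).
    Ties break toward smaller k, so a curve with no curvature (geometric
    decline, or an all-zero curve from degenerate constant data) returns the
    smallest eligible candidate.
    """
    if isinstance(sse_curve, dict):
        ks = sorted(sse_curve)
        vals = np.array([float(sse_curve[k]) for k in ks])
    else:
        vals = np.array([float(v) for v in sse_curve])
        ks = list(range(1, len(vals) + 1))
    if len(vals) < 3:
        raise ValueError("sse_curve needs at least 3 points")
    if np.any(np.diff(vals) > 1e-9):
        raise InvalidCurveError("SSE curve increases beyond tolerance")
    if vals[0] <= 1e-12:  # flat-at-zero degenerate curve
        return ks[0]
    eps = 1e-12 * max(vals[0], 1.0)
    logv = np.log(np.maximum(vals, eps))
    # second difference at interior point i: (v[i-1]-v[i]) - (v[i]-v[i+1])
    second = [
        (logv[i - 1] - logv[i]) - (logv[i] - logv[i + 1])
        for i in range(1, len(vals) - 1)
    ]
    best = int(np.argmax(second))  # argmax takes the first (smallest-k) tie
    return ks[1 + best]


class UnfittedModelError(RuntimeError):
    pass


def assign_subregions(svmap: SupervoxelMap, model: SubregionModel) -> "SubregionLabelMap":
    """Paint each supervoxel with its maximum-posterior canonical subregion."""
    if not model.fitted:
        raise UnfittedModelError("subregion model has no fitted components")
    x = svmap.phenotypes["mean_intensity"].to_numpy(dtype=float).reshape(-1, 1)
    # posterior under a 1-D Gaussian mixture, computed from stored parameters
    # so a deserialized model behaves identically to a freshly fitted one
    log_w = np.log(model.weights)
    var = model.variances
    log_pdf = (
        -0.5 * np.log(2 * np.pi * var)[None, :]
        - 0.5 * (x - model.means[None, :]) ** 2 / var[None, :]
    )
    comp = np.argmax(log_pdf + log_w[None, :], axis=1)
    canonical = model.label_order[comp]

    lut = np.zeros(svmap.n_supervoxels + 1, dtype=np.int32)
    lut[svmap.phenotypes["supervoxel"].to_numpy()] = canonical
    return SubregionLabelMap(labels=lut[svmap.labels], k=model.k)


@dataclass
class SubregionLabelMap:
    """Per-voxel subregion labels: 0 = background, 1..k = subregions."""

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.min() < 0 or self.labels.max() > self.k:
            raise ValueError("labels must lie in 0..k")


def subregion_stats(labelmap: SubregionLabelMap, hu_vol: CTVolume) -> pd.DataFrame:
    """Per-subregion mean HU, voxel count and volume proportion.

    A subregion absent from the lesion gets proportion 0 and an undefined
    (NaN) mean, flagged in the ``absent`` column rather than raised.
    """
    if labelmap.labels.shape != hu_vol.shape:
        raise ValueError("label map and HU volume are misaligned")
    lab = labelmap.labels
    n_mask = int((lab > 0).sum())
    rows = []
    for s in range(1, labelmap.k + 1):
        sel = lab == s
        n = int(sel.sum())
        rows.append(
            {
                "subregion": s,
                "mean_hu": float(hu_vol.voxels[sel].mean()) if n else np.nan,
                "n_voxels": n,
                "proportion": n / n_mask if n_mask else 0.0,
                "absent": n == 0,
            }
        )
    return pd.DataFrame(rows)


def model_to_dict(model: SubregionModel) -> dict:
    """Versioned JSON-serializable form of a fitted subregion model."""
    return {
        "format_version": 1,
        "k": int(model.k),
        "weights": [float(w) for w in model.weights],
        "means": [float(m) for m in model.means],
        "variances": [float(v) for v in model.variances],
        "label_order": [int(i) for i in model.label_order],
        "sse_curve": {str(k): float(v) for k, v in model.sse_curve.items()},
        "fit_seed": int(model.fit_seed),
        "sse_monotonized": bool(model.sse_monotonized),
    }


def model_from_dict(d: dict) -> SubregionModel:
    return SubregionModel(
        k=int(d["k"]),
        weights=np.asarray(d["weights"], dtype=float),
        means=np.asarray(d["means"], dtype=float),
        variances=np.asarray(d["variances"], dtype=float),
        label_order=np.asarray(d["label_order"], dtype=int),
        sse_curve={int(k): float(v) for k, v in d["sse_curve"].items()},
        fit_seed=int(d.get("fit_seed", 0)),
        sse_monotonized=bool(d.get("sse_monotonized", False)),
    )
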