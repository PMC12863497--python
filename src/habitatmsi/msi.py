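"""Multi-regional Spatial Interaction (MSI) matrix and derived features.

The MSI matrix is a (k+1)×(k+1) symmetric co-occurrence count matrix over
subregion labels {0..k} (0 = background): for every unordered pair of
neighbouring voxels — face adjacency by default — with at least one voxel
inside the lesion, the cell for the pair of labels is incremented. Diagonal
cells therefore scale with subregion volume and off-diagonal cells count the
inter-region border contacts. Pairs lying wholly in the background are never
counted, so N(0,0) = 0 and the matrix describes the lesion and its immediate
interface rather than the surrounding lung.

From the matrix (and the in-mask voxel counts carried with it) the extractor
derives 33 named first-order features — volume proportions, border
proportions, conditional border proportions, boundary shares, interior
ratios, a present-pair count and a pair entropy — and 5 second-order
Haralick-style statistics (contrast, correlation, energy, homogeneity,
entropy) on the normalized matrix P = N / ΣN with the integer labels 0..k as
gray levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .subregions import SubregionLabelMap

__all__ = [
    "MSIMatrix",
    "build_msi_matrix",
    "first_order_features",
    "second_order_features",
    "msi_feature_vector",
    "FIRST_ORDER_NAMES",
    "SECOND_ORDER_NAMES",
]

# half-space offsets: each unordered neighbour pair is visited exactly once
_OFFSETS_6 = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
_OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]


@dataclass
class MSIMatrix:
    """Symmetric label co-occurrence counts plus per-label voxel counts."""

    counts: np.ndarray  # (k+1, k+1) int64
    k: int
    connectivity: int
    voxel_counts: np.ndarray  # in-mask voxel count per label 1..k (length k)

    @property
    def probabilities(self) -> np.ndarray:
        """P(i,j) = N(i,j)/ΣN; sums to 1 for any non-empty lesion."""
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total

    @property
    def border_total(self) -> int:
        """B = Σ_{i<j} N(i,j): total inter-region border contacts."""
        iu = np.triu_indices(self.k + 1, k=1)
        return int(self.counts[iu].sum())


def build_msi_matrix(labelmap: SubregionLabelMap, connectivity: int = 6) -> MSIMatrix:
    """Count label co-occurrences over neighbouring voxel pairs.

    Each unordered neighbour pair with at least one in-mask voxel adds 1 to
    N(a, b) and, for a ≠ b, 1 to the mirror cell, keeping N symmetric.
    """
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    lab = np.asarray(labelmap.labels)
    k = labelmap.k
    if lab.min() < 0 or lab.max() > k:
        raise ValueError("labels outside 0..k")
    if not (lab > 0).any():
        raise ValueError("label map has no in-mask voxels")

    offsets = _OFFSETS_6 if connectivity == 6 else _OFFSETS_26
    n_cells = k + 1
    counts = np.zeros(n_cells * n_cells, dtype=np.int64)
    for off in offsets:
        sl_a = tuple(slice(None, -d) if d > 0 else slice(-d, None) for d in off)
        sl_b = tuple(slice(d, None) if d > 0 else slice(None, d or None) for d in off)
        a = lab[sl_a].ravel()
        b = lab[sl_b].ravel()
        keep = (a > 0) | (b > 0)
        np.add.at(counts, a[keep] * n_cells + b[keep], 1)
    m = counts.reshape(n_cells, n_cells)
    sym = m + m.T  # ordered -> each unordered pair once per cell + mirror
    np.fill_diagonal(sym, np.diagonal(m))
    voxel_counts = np.array([(lab == s).sum() for s in range(1, k + 1)], dtype=np.int64)
    return MSIMatrix(counts=sym, k=k, connectivity=connectivity, voxel_counts=voxel_counts)


def _ordered_pairs(k: int):
    return [(i, j) for i in range(k + 1) for j in range(k + 1) if i != j]


def _unordered_pairs(k: int):
    return [(i, j) for i in range(k + 1) for j in range(i + 1, k + 1)]


FIRST_ORDER_NAMES: tuple[str, ...] = tuple(
    [f"volume_proportion_{i}" for i in (1, 2, 3)]
    + ["background_interface_fraction"]
    + [f"MSI_border_proportion_{i}_{j}" for i, j in _unordered_pairs(3)]
    + [f"MSI_conditional_border_{i}_to_{j}" for i, j in _ordered_pairs(3)]
    + [f"region_boundary_share_{i}" for i in range(4)]
    + [f"interior_ratio_{i}" for i in (1, 2, 3)]
    + ["present_pair_count", "pair_entropy", "max_volume_proportion", "min_volume_proportion"]
)

SECOND_ORDER_NAMES: tuple[str, ...] = (
    "MSI_contrast",
    "MSI_correlation",
    "MSI_energy",
    "MSI_homogeneity",
    "MSI_entropy",
)


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    """0/0 -> 0 with a degeneracy flag."""
    if den == 0:
        return 0.0, True
    return num / den, False


def first_order_features(m: MSIMatrix) -> dict[str, float]:
    """The 33 named first-order MSI features (see module docstring).

    Proportions of absent regions follow the 0/0 → 0 convention; degeneracy
    flags are available via :func:`first_order_features_flagged`.
    """
    values, _ = first_order_features_flagged(m)
    return values


def first_order_features_flagged(m: MSIMatrix) -> tuple[dict[str, float], dict[str, bool]]:
    if m.k != 3:
        raise ValueError("first-order enumeration is defined for k = 3")
    N = m.counts.astype(float)
    V = m.voxel_counts.astype(float)
    v_total = V.sum()
    B = float(m.border_total)

    vals: dict[str, float] = {}
    flags: dict[str, bool] = {}

    def put(name, num, den):
        vals[name], flags[name] = _safe_div(num, den)

    for i in (1, 2, 3):
        put(f"volume_proportion_{i}", V[i - 1], v_total)
    put("background_interface_fraction", sum(N[0, j] for j in (1, 2, 3)), B)
    for i, j in _unordered_pairs(3):
        put(f"MSI_border_proportion_{i}_{j}", N[i, j], B)
    for i, j in _ordered_pairs(3):
        den = sum(N[i, jj] for jj in range(4) if jj != i)
        put(f"MSI_conditional_border_{i}_to_{j}", N[i, j], den)
    for i in range(4):
        put(f"region_boundary_share_{i}", sum(N[i, j] for j in range(4) if j != i), B)
    for i in (1, 2, 3):
        off = sum(N[i, j] for j in range(4) if j != i)
        put(f"interior_ratio_{i}", N[i, i], N[i, i] + off)

    pair_counts = np.array([N[i, j] for i, j in _unordered_pairs(3)])
    vals["present_pair_count"] = float((pair_counts > 0).sum())
    flags["present_pair_count"] = False
    if B > 0:
        p = pair_counts[pair_counts > 0] / B
        vals["pair_entropy"] = float(-(p * np.log2(p)).sum())
        flags["pair_entropy"] = False
    else:
        vals["pair_entropy"], flags["pair_entropy"] = 0.0, True
    vp = np.array([vals[f"volume_proportion_{i}"] for i in (1, 2, 3)])
    vals["max_volume_proportion"] = float(vp.max())
    vals["min_volume_proportion"] = float(vp.min())
    flags["max_volume_proportion"] = flags["min_volume_proportion"] = False

    ordered = {name: vals[name] for name in FIRST_ORDER_NAMES}
    return ordered, {name: flags[name] for name in FIRST_ORDER_NAMES}


def second_order_features(m: MSIMatrix) -> dict[str, float]:
    """Haralick-style statistics on P = N/ΣN with labels 0..k as gray levels.

    A degenerate matrix with zero marginal variance (all mass on one label)
    has correlation defined as 0.
    """
    P = m.probabilities
    n = P.shape[0]
    idx = np.arange(n, dtype=float)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")

    contrast = float(((ii - jj) ** 2 * P).sum())
    mu_r = float((ii * P).sum())
    mu_c = float((jj * P).sum())
    var_r = float(((ii - mu_r) ** 2 * P).sum())
    var_c = float(((jj - mu_c) ** 2 * P).sum())
    denom = np.sqrt(var_r * var_c)
    if denom > 0:
        correlation = float((((ii - mu_r) * (jj - mu_c) * P).sum()) / denom)
    else:
        correlation = 0.0
    energy = float((P**2).sum())
    homogeneity = float((P / (1.0 + np.abs(ii - jj))).sum())
    pos = P[P > 0]
    entropy = float(-(pos * np.log2(pos)).sum()) if pos.size else 0.0

    return {
        "MSI_contrast": contrast,
        "MSI_correlation": correlation,
        "MSI_energy": energy,
        "MSI_homogeneity": homogeneity,
        "MSI_entropy": entropy,
    }


def msi_feature_vector(
    labelmap: SubregionLabelMap, connectivity: int = 6
) -> dict[str, float]:
    """All 38 MSI features (33 first-order + 5 second-order), stably named."""
    m = build_msi_matrix(labelmap, connectivity=connectivity)
    out = first_order_features(m)
    out.update(second_order_features(m))
    return out
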