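"""Deterministic CT conditioning: window/level normalization, isotropic
resampling, VOI cropping and mask-overlap metrics.

The normalization convention follows lung-CT practice: clip HU to the display
window (default width 1500 HU, level −600 HU, i.e. [−1350, 150]) and map the
window affinely onto [0, 1]. Values outside the window saturate at 0/1 —
"max-min" scaling after windowing is only well defined with saturation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import AlignmentError, CTVolume, EmptyMaskError, LesionMask

__all__ = [
    "WindowSpec",
    "window_normalize",
    "resample_isotropic",
    "crop_voi",
    "dice",
]


@dataclass(frozen=True)
class WindowSpec:
    """CT display window: ``width`` HU centred on ``level`` HU."""

    width: float = 1500.0
    level: float = -600.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be positive")

    @property
    def low(self) -> float:
        return self.level - self.width / 2.0

    @property
    def high(self) -> float:
        return self.level + self.width / 2.0


def window_normalize(vol: CTVolume, w: WindowSpec = WindowSpec()) -> CTVolume:
    """Clip HU to the window and rescale to [0, 1].

    Monotone non-decreasing in HU; with the defaults the window is
    [−1350, 150] so −600 HU maps to 0.5.
    """
    if vol.value_domain != "HU":
        raise ValueError("window_normalize expects an HU-domain volume")
    clipped = np.clip(vol.voxels.astype(np.float64), w.low, w.high)
    unit = (clipped - w.low) / w.width
    return vol.with_voxels(unit, value_domain="unit")


def _target_shape(shape, spacing, target) -> tuple[int, ...]:
    # out_dim = round(in_dim * in_spacing / target), at least 1 per axis
    return tuple(
        max(1, int(round(d * s / t))) for d, s, t in zip(shape, spacing, target)
    )


def resample_isotropic(
    vol: CTVolume | LesionMask,
    target_mm=(1.0, 1.0, 1.0),
    order: int | None = None,
) -> CTVolume | LesionMask:
    """Resample a volume or mask to the target spacing.

    Intensities use cubic spline interpolation by default; masks use
    nearest-neighbour so labels stay binary. Output dimensions follow
    ``round(in_dim * in_spacing / target)``.
    """
    target = tuple(float(t) for t in np.atleast_1d(target_mm).repeat(
        3 if np.ndim(target_mm) == 0 else 1)[:3])
    if len(target) != 3:
        target = (target[0],) * 3
    if any(t <= 0 for t in target):
        raise ValueError("target spacing must be positive")

    is_mask = isinstance(vol, LesionMask)
    if order is None:
        order = 0 if is_mask else 3
    new_shape = _target_shape(vol.shape, vol.spacing, target)
    if new_shape == vol.shape and tuple(vol.spacing) == target:
        return vol
    zoom = [n / o for n, o in zip(new_shape, vol.shape)]
    data = vol.voxels.astype(np.float64)
    out = ndimage.zoom(data, zoom, order=order, mode="nearest", grid_mode=True)
    out = out[: new_shape[0], : new_shape[1], : new_shape[2]]
    if is_mask:
        return LesionMask(out > 0.5, target, vol.origin)
    return CTVolume(
        np.clip(out, 0.0, 1.0) if vol.value_domain == "unit" else out,
        target,
        vol.origin,
        vol.value_domain,
    )


def crop_voi(
    vol: CTVolume, mask: LesionMask, margin_vox: int = 0
) -> tuple[CTVolume, LesionMask]:
    """Crop both grids to the mask bounding box expanded by ``margin_vox``.

    The expanded box is clipped to the image extent (no padding), so a
    margin larger than the image returns the full grids.
    """
    mask.check_aligned(vol)
    if margin_vox < 0:
        raise ValueError("margin_vox must be non-negative")
    if mask.n_foreground == 0:
        raise EmptyMaskError("cannot crop around an empty mask")
    idx = np.nonzero(mask.voxels)
    sl = tuple(
        slice(max(0, int(ax.min()) - margin_vox), min(n, int(ax.max()) + margin_vox + 1))
        for ax, n in zip(idx, mask.shape)
    )
    return (
        CTVolume(vol.voxels[sl], vol.spacing, vol.origin, vol.value_domain),
        LesionMask(mask.voxels[sl], mask.spacing, mask.origin),
    )


def dice(a: LesionMask, b: LesionMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|).

    Two empty masks are defined to agree perfectly (Dice 1), a documented
    convention for degenerate comparisons.
    """
    if a.shape != b.shape:
        raise AlignmentError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = a.n_foreground, b.n_foreground
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(a.voxels, b.voxels).sum())
    return 2.0 * inter / (na + nb)
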