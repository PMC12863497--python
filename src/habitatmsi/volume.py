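"""In-memory containers for CT volumes and lesion masks, with NIfTI-1 I/O.

The pipeline works on Hounsfield-unit (HU) voxel grids with millimetre
spacing metadata. ``CTVolume`` tracks whether its values are raw HU or have
been window-normalized to the unit interval, so downstream stages can assert
the domain they require.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = ["CTVolume", "LesionMask", "load_nifti_pair", "save_nifti_pair"]


class AlignmentError(ValueError):
    """Two grids that must share shape/spacing do not."""


class EmptyMaskError(ValueError):
    """An operation requiring foreground voxels received an empty mask."""


@dataclass
class CTVolume:
    """A 3-D scalar grid with geometry metadata.

    Parameters
    ----------
    voxels : ndarray
        3-D array; HU-valued or unit-valued depending on ``value_domain``.
    spacing : tuple of float
        Voxel edge lengths in mm per axis; strictly positive.
    origin : tuple of float
        Physical position of voxel (0,0,0) in mm.
    value_domain : str
        ``"HU"`` or ``"unit"``; unit-domain values must lie in [0, 1].
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    value_domain: str = "HU"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("CTVolume requires a 3-D voxel grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.value_domain not in ("HU", "unit"):
            raise ValueError("value_domain must be 'HU' or 'unit'")
        if self.value_domain == "unit":
            lo, hi = float(np.min(self.voxels)), float(np.max(self.voxels))
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValueError("unit-domain values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def with_voxels(self, voxels: np.ndarray, **kw) -> "CTVolume":
        return replace(self, voxels=voxels, **kw)


@dataclass
class LesionMask:
    """Binary lesion mask aligned to a :class:`CTVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("LesionMask requires a 3-D grid")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    def check_aligned(self, other) -> None:
        if self.shape != other.shape:
            raise AlignmentError(
                f"shape mismatch: {self.shape} vs {other.shape}"
            )


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0]).astype(float)
    aff[:3, 3] = origin
    return aff


def save_nifti_pair(vol: CTVolume, mask: LesionMask, image_path, mask_path) -> None:
    """Write an image/mask pair as NIfTI-1 with spacing in the affine."""
    aff = _affine(vol.spacing, vol.origin)
    nib.save(nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float32), aff), str(image_path))
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), aff), str(mask_path))


def load_nifti_pair(image_path, mask_path) -> tuple[CTVolume, LesionMask]:
    """Load an image/mask pair written by :func:`save_nifti_pair`."""
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    vol = CTVolume(np.asarray(img.dataobj, dtype=np.float64), spacing, origin, "HU")
    mask = LesionMask(np.asarray(msk.dataobj) > 0, spacing, origin)
    return vol, mask
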