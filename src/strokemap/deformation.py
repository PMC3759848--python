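"""Deformation-derived quantities: Jacobian maps, ROI volumes, lesion rule.

A displacement field u(x), stored in voxel units on the reference grid,
describes the non-rigid mapping of each subject image onto the reference.
Its Jacobian determinant J(x) = det(I + grad u) is the local fractional
volume change: J > 1 apparent expansion, J < 1 contraction, dV = J - 1 the
local apparent volume difference.  Because u is expressed in voxel units
and differentiated with respect to voxel index, J is a pure (dimensionless)
ratio irrespective of the anisotropy of the voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class JacobianMap:
    """Per-voxel Jacobian determinant of a displacement field.

    ``j`` is the determinant map; ``invalid`` flags voxels where J <= 0
    (a folded, non-diffeomorphic mapping).  ``log_j`` is defined only where
    J > 0 and is NaN at invalid voxels — invalid voxels are excluded from
    downstream statistics rather than clamped.
    """

    j: np.ndarray
    voxel_dims_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def invalid(self) -> np.ndarray:
        return self.j <= 0

    @property
    def log_j(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            lj = np.where(self.j > 0, np.log(np.maximum(self.j, 1e-300)), np.nan)
        return lj

    @property
    def dv(self) -> np.ndarray:
        """Local apparent volume difference J - 1."""
        return self.j - 1.0


def displacement_gradient(field: np.ndarray) -> np.ndarray:
    """Gradient tensor du_i/dx_j of a (X, Y, Z, 3) voxel-unit field.

    Central differences at interior voxels, one-sided at grid borders.
    Returns an array of shape (X, Y, Z, 3, 3).
    """
    field = np.asarray(field, dtype=float)
    if field.ndim != 4 or field.shape[-1] != 3:
        raise ValueError("field must have shape (X, Y, Z, 3)")
    if min(field.shape[:3]) < 3:
        raise ValueError("grid must span at least 3 voxels per axis")
    grad = np.empty(field.shape[:3] + (3, 3), dtype=float)
    for i in range(3):
        gx, gy, gz = np.gradient(field[..., i], axis=(0, 1, 2))
        grad[..., i, 0] = gx
        grad[..., i, 1] = gy
        grad[..., i, 2] = gz
    return grad


def jacobian_determinant(
    field: np.ndarray,
    voxel_dims_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> JacobianMap:
    """Convert a displacement field into its Jacobian determinant map.

    ``J(x) = det(I + grad u(x))`` evaluated voxelwise.  Non-finite field
    values are rejected with the offending voxel coordinates reported.
    """
    field = np.asarray(field, dtype=float)
    bad = ~np.isfinite(field)
    if bad.any():
        where = np.argwhere(bad.any(axis=-1))[:5]
        raise ValueError(
            f"non-finite displacement values at voxels {where.tolist()} ..."
        )
    g = displacement_gradient(field)
    g[..., 0, 0] += 1.0
    g[..., 1, 1] += 1.0
    g[..., 2, 2] += 1.0
    # cofactor expansion of the 3x3 determinant, vectorised over the grid
    j = (
        g[..., 0, 0] * (g[..., 1, 1] * g[..., 2, 2] - g[..., 1, 2] * g[..., 2, 1])
        - g[..., 0, 1] * (g[..., 1, 0] * g[..., 2, 2] - g[..., 1, 2] * g[..., 2, 0])
        + g[..., 0, 2] * (g[..., 1, 0] * g[..., 2, 1] - g[..., 1, 1] * g[..., 2, 0])
    )
    return JacobianMap(j=j, voxel_dims_mm=tuple(voxel_dims_mm))


def roi_volume(mask: np.ndarray, voxel_dims_mm) -> float:
    """Volume of a binary ROI in mm^3: voxel count times voxel volume."""
    mask = np.asarray(mask).astype(bool)
    return float(mask.sum()) * float(np.prod(voxel_dims_mm))


def hyperintensity_lesion_mask(
    volume: np.ndarray,
    contralateral_roi: np.ndarray,
    search_roi: np.ndarray,
) -> np.ndarray:
    """Threshold-based lesion definition against a homologous reference.

    A voxel inside ``search_roi`` is lesioned when its intensity exceeds the
    mean plus one standard deviation of the intensities in the homologous
    ``contralateral_roi`` of the unaffected hemisphere.  A constant
    reference region (SD = 0) degrades the rule to a pure mean threshold,
    with a warning.
    """
    volume = np.asarray(volume, dtype=float)
    contra = np.asarray(contralateral_roi).astype(bool)
    search = np.asarray(search_roi).astype(bool)
    if not contra.any():
        raise ValueError("contralateral reference ROI is empty")
    ref = volume[contra]
    sd = ref.std(ddof=1) if ref.size > 1 else 0.0
    if sd == 0.0:
        warnings.warn(
            "contralateral ROI has zero variance; thresholding at the mean",
            stacklevel=2,
        )
    threshold = ref.mean() + sd
    return search & (volume > threshold)


def mirror_mask(mask: np.ndarray, axis: int = 0) -> np.ndarray:
    """Reflect a mask across the grid midline along ``axis``.

    With the fixed mid-sagittal plane convention this maps an ipsilateral
    ROI onto its homologous contralateral region.
    """
    return np.flip(np.asarray(mask), axis=axis)
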