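"""Pull (sample) and push (splat) deformation operators.

``pull`` deforms a reference image to a motion state by trilinear sampling
at r + delta(r).  The exact inverse deformation generally does not exist, so
the approximate inverse warp is the *normalized push*: the exact adjoint
splat divided by the splat of a ones-image, which accounts for how many
voxels land in each target voxel.

Displacements are stored in mm (world space) and converted to voxel units
per axis inside the operators, which keeps anisotropic voxels correct.
Samples outside the grid read as 0 (air) and splats outside the grid are
dropped.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .geometry import ValidationError, Volume
from .motion import MotionField

__all__ = ["pull", "push", "compose_check", "displacement_to_voxels"]


def displacement_to_voxels(field: MotionField) -> np.ndarray:
    """Convert a mm displacement field to per-axis voxel units (C-contiguous)."""
    vox = np.asarray(field.grid.voxel_size_mm)
    return np.ascontiguousarray(field.displacement / vox)


def _check_grids(img: Volume, field: MotionField) -> None:
    if img.grid.shape != field.grid.shape or not np.allclose(
        img.grid.voxel_size_mm, field.grid.voxel_size_mm
    ):
        raise ValidationError("image grid and motion-field grid do not match")


def pull(img: Volume, field: MotionField) -> Volume:
    """out[r] = img[r + delta(r)] via trilinear interpolation."""
    _check_grids(img, field)
    disp = displacement_to_voxels(field)
    out = np.empty(img.grid.shape)
    _kernels.pull3(np.ascontiguousarray(img.values), disp, out)
    return Volume(img.grid, out)


def pull_with_gradient(img: Volume, field: MotionField):
    """Pull plus the exact gradient of the warped image w.r.t. delta (per mm)."""
    _check_grids(img, field)
    disp = displacement_to_voxels(field)
    out = np.empty(img.grid.shape)
    grad = np.empty((*img.grid.shape, 3))
    _kernels.pull3_grad(np.ascontiguousarray(img.values), disp, out, grad)
    grad /= np.asarray(img.grid.voxel_size_mm)  # voxel-unit -> per-mm derivative
    return Volume(img.grid, out), grad


def push(img: Volume, field: MotionField, normalized: bool = True) -> Volume:
    """Splat img along the field; the raw mode is the exact adjoint of pull.

    Normalized mode divides by the splat of a ones-image (zero-weight voxels
    are set to 0) and approximates the inverse warp.
    """
    _check_grids(img, field)
    disp = displacement_to_voxels(field)
    out = np.zeros(img.grid.shape)
    _kernels.push3(np.ascontiguousarray(img.values), disp, out)
    if not normalized:
        return Volume(img.grid, out)
    weights = np.zeros(img.grid.shape)
    _kernels.push3(np.ones(img.grid.shape), disp, weights)
    result = np.zeros(img.grid.shape)
    nz = weights > 0
    result[nz] = out[nz] / weights[nz]
    return Volume(img.grid, result)


def compose_check(img: Volume, field: MotionField) -> float:
    """Relative residual of the approximate-inverse round trip.

    Returns ||push_norm(pull(img, D), D) - img|| / ||img||; small values mean
    the normalized push is a good inverse of the pull for this field.
    """
    warped = pull(img, field)
    back = push(warped, field, normalized=True)
    denom = float(np.linalg.norm(img.values))
    if denom == 0.0:
        return 0.0
    return float(np.linalg.norm(back.values - img.values)) / denom
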