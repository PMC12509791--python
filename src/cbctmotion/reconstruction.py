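"""Motion-compensated SIRT image reconstruction.

Each iteration applies

    x <- x + C * sum_t Winv_t{ A_t^T R_t (y_t - A_t W_t{x}) }

with the standard SIRT normalizations C = 1 / (sum_t A_t^T 1_P) and
R_t = 1 / (A_t 1_I), elementwise and floored; W_t is the pull warp to the
motion state of frame t and Winv_t the normalized push back to the
reference state.  With identity motion the warps drop out and the update is
plain SIRT.  A non-negativity clamp is applied after every iteration by
default (attenuation is physical).

The reconstruction domain is the supplied field-of-view grid extended
transversally by a configurable margin, because the object commonly extends
beyond the FOV and truncated rays otherwise project their mass inside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ProjectionSet, ScanGeometry, ValidationError, Volume, VolumeGrid
from .motion import MotionField, MotionParameters
from .projector import back_project, forward_project
from .warping import pull, push

__all__ = [
    "SIRTConfig",
    "sirt_reconstruct",
    "motion_corrupted_reconstruct",
    "crop_to_grid",
]


@dataclass(frozen=True)
class SIRTConfig:
    n_iterations: int = 200
    nonnegativity: bool = True
    extended_domain_margin: float = 0.25
    normalization_floor_rel: float = 1.0e-6

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        if self.extended_domain_margin < 0:
            raise ValidationError("extended_domain_margin must be >= 0")


def _floored_inverse(arr: np.ndarray, rel_floor: float) -> np.ndarray:
    """1/arr with entries below rel_floor * median(positive entries) floored."""
    pos = arr[arr > 0]
    floor = rel_floor * float(np.median(pos)) if pos.size else 1.0
    floor = max(floor, np.finfo(float).tiny)
    return 1.0 / np.maximum(arr, floor)


def sirt_reconstruct(
    projections: ProjectionSet,
    geom: ScanGeometry,
    grid: VolumeGrid,
    motion: MotionParameters | None = None,
    config: SIRTConfig = SIRTConfig(),
    initial: Volume | None = None,
    pad_domain: bool = True,
    callback=None,
) -> Volume:
    """Run motion-compensated SIRT; ``motion=None`` means identity motion.

    ``grid`` is the field-of-view grid; the iteration runs on the extended
    grid (``config.extended_domain_margin`` per transverse side) and the
    returned volume carries the extended grid with the FOV recorded in
    ``meta``.  Use :func:`crop_to_grid` to recover the FOV volume.
    """
    if projections.domain != "line_integral":
        raise ValidationError("SIRT expects line-integral projections")
    if projections.n_frames != geom.n_frames:
        raise ValidationError("projection frame count does not match geometry")

    rgrid = grid.padded(config.extended_domain_margin) if pad_domain else grid
    T = geom.n_frames

    # motion-model fields, evaluated lazily per frame (they are frame-constant
    # across iterations but too large to store for every frame)
    if motion is not None:
        sigma = motion.spatial_fields(rgrid)  # (nc, 3, nx, ny, nz)
        tau = motion.temporal_profiles(geom.timestamps_s)  # (nc, T)

        def frame_field(t: int) -> MotionField:
            delta = np.tensordot(tau[:, t], sigma, axes=(0, 0))
            return MotionField(
                rgrid,
                np.ascontiguousarray(np.moveaxis(delta, 0, -1)),
                float(geom.timestamps_s[t]),
            )

    # normalizations
    ones_vol = Volume(rgrid, np.ones(rgrid.shape))
    R = np.empty((T, geom.detector_rows, geom.detector_cols))
    for t in range(T):
        R[t] = _floored_inverse(
            forward_project(ones_vol, geom, t, check_finite=False),
            config.normalization_floor_rel,
        )
    col_sum = np.zeros(rgrid.shape)
    ones_proj = np.ones((geom.detector_rows, geom.detector_cols))
    for t in range(T):
        col_sum += back_project(ones_proj, geom, t, rgrid).values
    C = _floored_inverse(col_sum, config.normalization_floor_rel)

    if initial is not None:
        if initial.grid.shape != rgrid.shape:
            raise ValidationError("warm-start volume must live on the extended grid")
        x = initial.values.copy()
    else:
        x = np.zeros(rgrid.shape)

    residual_norms = []
    for n in range(config.n_iterations):
        update = np.zeros(rgrid.shape)
        sq_resid = 0.0
        for t in range(T):
            if motion is not None:
                fld = frame_field(t)
                xt = pull(Volume(rgrid, x), fld)
            else:
                xt = Volume(rgrid, x)
            resid = projections.values[t] - forward_project(
                xt, geom, t, check_finite=False
            )
            sq_resid += float(np.sum(resid * resid))
            b = back_project(R[t] * resid, geom, t, rgrid)
            if motion is not None:
                b = push(b, fld, normalized=True)
            update += b.values
        x = x + C * update
        if config.nonnegativity:
            np.maximum(x, 0.0, out=x)
        rn = float(np.sqrt(sq_resid))
        if not np.isfinite(rn) or not np.isfinite(x).all():
            raise RuntimeError(f"SIRT diverged: non-finite values at iteration {n}")
        residual_norms.append(rn)
        if callback is not None:
            callback(n, rn)

    meta = {
        "fov_shape": grid.shape,
        "fov_origin_mm": grid.origin_mm,
        "residual_norms": residual_norms,
        "motion_compensated": motion is not None,
    }
    return Volume(rgrid, x, meta)


def motion_corrupted_reconstruct(
    projections: ProjectionSet,
    geom: ScanGeometry,
    grid: VolumeGrid,
    config: SIRTConfig = SIRTConfig(),
    **kwargs,
) -> Volume:
    """Plain SIRT without motion compensation; the initial reference x0."""
    return sirt_reconstruct(projections, geom, grid, motion=None, config=config, **kwargs)


def crop_to_grid(vol: Volume, grid: VolumeGrid) -> Volume:
    """Extract the sub-volume of ``vol`` living on ``grid`` (same spacing)."""
    if not np.allclose(vol.grid.voxel_size_mm, grid.voxel_size_mm):
        raise ValidationError("grids must share voxel size for cropping")
    start = [
        int(round((grid.origin_mm[a] - vol.grid.origin_mm[a]) / vol.grid.voxel_size_mm[a]))
        for a in range(3)
    ]
    sl = tuple(slice(s, s + n) for s, n in zip(start, grid.shape))
    if any(s.start < 0 or s.stop > vol.grid.shape[a] for a, s in enumerate(sl)):
        raise ValidationError("target grid is not contained in the volume")
    return Volume(grid, vol.values[sl].copy(), dict(vol.meta))
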