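"""Forward/back projection operator pair and the counts <-> line-integral maps.

``forward_project`` implements the per-frame system matrix A_t (Joseph ray
tracing through a trilinear volume model); ``back_project`` is its exact
algebraic transpose A_t^T.  ``log_transform`` linearizes raw detector counts
s into attenuation line integrals y = -ln(s / s0).
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .geometry import ProjectionSet, ScanGeometry, ValidationError, Volume, VolumeGrid

__all__ = [
    "forward_project",
    "back_project",
    "project_all",
    "log_transform",
    "estimate_source_intensity",
]

#: counts floor applied before the log; detector zeros occur under heavy noise
DEFAULT_COUNTS_FLOOR = 1.0


def _frame_arrays(geom: ScanGeometry, frame: int):
    if not (0 <= frame < geom.n_frames):
        raise IndexError(f"frame {frame} out of range [0, {geom.n_frames})")
    src = np.ascontiguousarray(geom.source_position(frame))
    center, u_axis, v_axis = geom.detector_frame(frame)
    return (
        src,
        np.ascontiguousarray(center),
        np.ascontiguousarray(u_axis),
        np.ascontiguousarray(v_axis),
        float(geom.pixel_spacing_mm[1]),
        float(geom.pixel_spacing_mm[0]),
    )


def forward_project(
    vol: Volume, geom: ScanGeometry, frame: int, check_finite: bool = True
) -> np.ndarray:
    """Line-integral image y_t = A_t x for one frame (attenuation * mm)."""
    if check_finite:
        vol.require_finite()
    src, center, u_axis, v_axis, pu, pv = _frame_arrays(geom, frame)
    grid = vol.grid
    out = np.zeros((geom.detector_rows, geom.detector_cols))
    _kernels.joseph_forward(
        np.ascontiguousarray(vol.values),
        np.asarray(grid.origin_mm),
        np.asarray(grid.voxel_size_mm),
        src,
        center,
        u_axis,
        v_axis,
        pu,
        pv,
        out,
    )
    return out


def back_project(
    proj: np.ndarray, geom: ScanGeometry, frame: int, grid: VolumeGrid
) -> Volume:
    """A_t^T p: exact adjoint of :func:`forward_project`."""
    proj = np.asarray(proj, dtype=np.float64)
    if proj.shape != (geom.detector_rows, geom.detector_cols):
        raise ValidationError(
            f"projection shape {proj.shape} != detector grid "
            f"({geom.detector_rows}, {geom.detector_cols})"
        )
    src, center, u_axis, v_axis, pu, pv = _frame_arrays(geom, frame)
    out = np.zeros(grid.shape)
    _kernels.joseph_backward(
        np.ascontiguousarray(proj),
        np.asarray(grid.origin_mm),
        np.asarray(grid.voxel_size_mm),
        src,
        center,
        u_axis,
        v_axis,
        pu,
        pv,
        out,
    )
    return Volume(grid, out)


def project_all(vol: Volume, geom: ScanGeometry) -> ProjectionSet:
    """Forward project a static volume for every frame."""
    vol.require_finite()
    stack = np.empty((geom.n_frames, geom.detector_rows, geom.detector_cols))
    for t in range(geom.n_frames):
        stack[t] = forward_project(vol, geom, t, check_finite=False)
    return ProjectionSet(geom, stack, domain="line_integral")


def log_transform(
    s: ProjectionSet, s0: float, counts_floor: float = DEFAULT_COUNTS_FLOOR
) -> ProjectionSet:
    """Counts -> line integrals: y = -ln(max(s, floor) / s0)."""
    if s0 <= 0:
        raise ValidationError("source intensity s0 must be positive")
    if s.domain != "counts":
        raise ValidationError("log_transform expects counts-domain projections")
    y = -np.log(np.maximum(s.values, counts_floor) / s0)
    return ProjectionSet(s.geometry, y, domain="line_integral")


def estimate_source_intensity(s: ProjectionSet, background_region) -> float:
    """Mean counts over a background (air) detector ROI across all frames.

    ``background_region`` is ``(row_slice, col_slice)`` in detector indices.
    """
    if s.domain != "counts":
        raise ValidationError("source intensity is estimated from counts data")
    row_sl, col_sl = background_region
    rows = range(*row_sl.indices(s.geometry.detector_rows))
    cols = range(*col_sl.indices(s.geometry.detector_cols))
    if len(rows) == 0 or len(cols) == 0:
        raise ValidationError("background ROI is empty or outside the detector")
    for sl, n in ((row_sl, s.geometry.detector_rows), (col_sl, s.geometry.detector_cols)):
        if sl.start is not None and (sl.start < 0 or sl.start >= n):
            raise ValidationError("background ROI extends outside the detector")
        if sl.stop is not None and sl.stop > n:
            raise ValidationError("background ROI extends outside the detector")
    return float(np.mean(s.values[:, row_sl, col_sl]))
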