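"""Low-rank spatio-temporal cubic-B-spline motion model.

A displacement field is represented as a sum of ``n_components`` separable
rank-1 terms: a 3D spatial vector field sigma_c(r) (tensor-product cubic
B-splines with coefficients in mm) scaled by a scalar temporal profile
tau_c(t) (1D cubic B-spline, unitless coefficients):

    D_t(r) = r + sum_c sigma_c(r) * tau_c(t)

Both bases use uniformly spaced, clamped (open-uniform) knots spanning the
reconstruction grid and the scan duration exactly, so the partition of unity
holds on the whole domain and displacements vanish nowhere artificially.
The spatial/temporal split is deliberately left unnormalized (the bilinear
product carries a gauge freedom; only the product is identifiable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.interpolate import BSpline

from .geometry import ValidationError, VolumeGrid

__all__ = [
    "SplineConfig",
    "MotionParameters",
    "MotionField",
    "bspline_design_matrix",
    "spatial_basis",
    "temporal_basis",
    "evaluate_motion_field",
    "motion_jacobian",
]

DEGREE = 3  # cubic


def clamped_knots(a: float, b: float, n_ctrl: int) -> np.ndarray:
    """Open-uniform (clamped) knot vector on [a, b] for cubic splines."""
    if n_ctrl < DEGREE + 1:
        raise ValidationError(f"need >= {DEGREE + 1} control points, got {n_ctrl}")
    interior = np.linspace(a, b, n_ctrl - DEGREE + 1)
    return np.concatenate([[a] * DEGREE, interior, [b] * DEGREE])


def bspline_design_matrix(
    x: np.ndarray, a: float, b: float, n_ctrl: int, deriv: int = 0
) -> np.ndarray:
    """Dense (len(x), n_ctrl) matrix of clamped cubic B-spline basis values.

    Evaluation points are clamped into [a, b]; ``deriv`` selects the basis
    functions themselves or an analytic derivative order.
    """
    t = clamped_knots(a, b, n_ctrl)
    x = np.clip(np.asarray(x, dtype=np.float64), a, b)
    if deriv == 0:
        # scipy evaluates all basis elements at once; guard the right edge
        span = max(b - a, np.finfo(float).tiny)
        xe = np.minimum(x, b - 1e-13 * span)
        return BSpline.design_matrix(xe, t, DEGREE, extrapolate=False).toarray()
    cols = np.empty((len(x), n_ctrl))
    for j in range(n_ctrl):
        coeff = np.zeros(n_ctrl)
        coeff[j] = 1.0
        cols[:, j] = BSpline(t, coeff, DEGREE, extrapolate=False).derivative(deriv)(x)
    return np.nan_to_num(cols)


@dataclass(frozen=True)
class SplineConfig:
    """Knot layout of the motion model.

    ``spatial_control_points_per_dim`` counts coefficients per axis (>= 4 for
    cubic support); ``temporal_control_point_rate`` is the temporal knot
    density in control points per second of scan time.
    """

    spatial_control_points_per_dim: Tuple[int, int, int] = (32, 32, 32)
    temporal_control_point_rate: float = 2.0

    def __post_init__(self) -> None:
        cp = self.spatial_control_points_per_dim
        if isinstance(cp, int):
            cp = (cp, cp, cp)
        cp = tuple(int(n) for n in cp)
        object.__setattr__(self, "spatial_control_points_per_dim", cp)
        if any(n < DEGREE + 1 for n in cp):
            raise ValidationError("need >= 4 spatial control points per dimension")
        if self.temporal_control_point_rate <= 0:
            raise ValidationError("temporal control point rate must be > 0")

    def n_temporal_segments(self, duration_s: float) -> int:
        return max(1, int(round(self.temporal_control_point_rate * duration_s)))

    def n_temporal_ctrl(self, duration_s: float) -> int:
        # clamped cubic basis over m uniform segments has m + 3 coefficients
        return self.n_temporal_segments(duration_s) + DEGREE


def _axis_domain(grid: VolumeGrid, axis: int) -> Tuple[float, float]:
    c = grid.axis_coordinates(axis)
    return float(c[0]), float(c[-1]) if len(c) > 1 else (float(c[0]) + 1.0)


def spatial_basis(
    config: SplineConfig,
    grid: VolumeGrid,
    deriv_axis: int | None = None,
    domain=None,
):
    """Per-axis basis matrices (Bx, By, Bz) evaluated at voxel centers.

    With ``deriv_axis`` set, that axis' matrix holds first derivatives
    (per mm) instead of basis values.  ``domain`` optionally fixes the
    per-axis knot span ``((ax, bx), (ay, by), (az, bz))`` independently of
    the evaluation grid (the default span is the grid itself).
    """
    mats = []
    for axis in range(3):
        a, b = _axis_domain(grid, axis) if domain is None else domain[axis]
        n_ctrl = config.spatial_control_points_per_dim[axis]
        deriv = 1 if deriv_axis == axis else 0
        mats.append(
            bspline_design_matrix(grid.axis_coordinates(axis), a, b, n_ctrl, deriv)
        )
    return tuple(mats)


def temporal_basis(
    config: SplineConfig,
    timestamps: np.ndarray,
    domain: Tuple[float, float] | None = None,
) -> np.ndarray:
    """(n_frames, n_temporal_ctrl) basis matrix; rows sum to 1."""
    timestamps = np.atleast_1d(np.asarray(timestamps, dtype=np.float64))
    if timestamps.size == 0:
        raise ValidationError("timestamps must be non-empty")
    if domain is None:
        domain = (float(timestamps[0]), float(timestamps[-1]))
    t0, t1 = domain
    duration = max(t1 - t0, 1e-9)
    n_ctrl = config.n_temporal_ctrl(duration)
    return bspline_design_matrix(timestamps, t0, t1, n_ctrl)


def expand_spatial(Bx, By, Bz, coeff: np.ndarray) -> np.ndarray:
    """Tensor-product expansion of one coefficient block onto the voxel grid."""
    return np.einsum("xi,yj,zk,ijk->xyz", Bx, By, Bz, coeff, optimize=True)


def contract_spatial(Bx, By, Bz, field: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`expand_spatial` (voxel field -> coefficient block)."""
    return np.einsum("xi,yj,zk,xyz->ijk", Bx, By, Bz, field, optimize=True)


@dataclass
class MotionParameters:
    """Coefficients of the low-rank motion model.

    ``spatial`` has shape (n_components, 3, ncx, ncy, ncz) in mm;
    ``temporal`` has shape (n_components, n_temporal_ctrl), unitless.
    ``temporal_domain`` is the (first, last) scan time the temporal basis
    spans.
    """

    config: SplineConfig
    spatial: np.ndarray
    temporal: np.ndarray
    temporal_domain: Tuple[float, float]
    #: per-axis world span ((ax, bx), (ay, by), (az, bz)) of the spatial knot
    #: vector.  When None the basis spans whichever grid the field is
    #: evaluated on; set it whenever fields must stay consistent across
    #: grids (e.g. FOV vs extended reconstruction domain).
    spatial_domain: tuple | None = None

    def __post_init__(self) -> None:
        self.spatial = np.asarray(self.spatial, dtype=np.float64)
        self.temporal = np.asarray(self.temporal, dtype=np.float64)
        cp = self.config.spatial_control_points_per_dim
        if self.spatial.ndim != 5 or self.spatial.shape[1:] != (3, *cp):
            raise ValidationError(
                f"spatial coefficients shape {self.spatial.shape} inconsistent "
                f"with config {(self.spatial.shape[0], 3, *cp)}"
            )
        duration = self.temporal_domain[1] - self.temporal_domain[0]
        n_t = self.config.n_temporal_ctrl(duration)
        if self.temporal.shape != (self.spatial.shape[0], n_t):
            raise ValidationError(
                f"temporal coefficients shape {self.temporal.shape} != "
                f"{(self.spatial.shape[0], n_t)}"
            )
        if self.n_components < 1:
            raise ValidationError("motion model needs at least one component")
        if not (np.all(np.isfinite(self.spatial)) and np.all(np.isfinite(self.temporal))):
            raise ValidationError("motion coefficients must be finite")

    @property
    def n_components(self) -> int:
        return self.spatial.shape[0]

    @property
    def n_parameters(self) -> int:
        return self.spatial.size + self.temporal.size

    @classmethod
    def zeros(
        cls,
        config: SplineConfig,
        temporal_domain: Tuple[float, float],
        n_components: int = 1,
        spatial_domain: tuple | None = None,
    ) -> "MotionParameters":
        if n_components < 1:
            raise ValidationError("n_components must be >= 1")
        cp = config.spatial_control_points_per_dim
        duration = temporal_domain[1] - temporal_domain[0]
        n_t = config.n_temporal_ctrl(duration)
        return cls(
            config,
            np.zeros((n_components, 3, *cp)),
            np.zeros((n_components, n_t)),
            (float(temporal_domain[0]), float(temporal_domain[1])),
            spatial_domain,
        )

    @staticmethod
    def domain_of(grid: VolumeGrid) -> tuple:
        """Per-axis world span of a grid, usable as ``spatial_domain``."""
        return tuple(_axis_domain(grid, a) for a in range(3))

    def temporal_profiles(self, timestamps: np.ndarray) -> np.ndarray:
        """tau_c(t) for every component: shape (n_components, n_frames)."""
        Bt = temporal_basis(self.config, timestamps, self.temporal_domain)
        return self.temporal @ Bt.T

    def spatial_fields(self, grid: VolumeGrid) -> np.ndarray:
        """sigma_c(r): dense (n_components, 3, nx, ny, nz) array in mm."""
        Bx, By, Bz = spatial_basis(self.config, grid, domain=self.spatial_domain)
        out = np.empty((self.n_components, 3, *grid.shape))
        for c in range(self.n_components):
            for p in range(3):
                out[c, p] = expand_spatial(Bx, By, Bz, self.spatial[c, p])
        return out


@dataclass
class MotionField:
    """Dense displacement field delta_t(r) in mm at one time frame."""

    grid: VolumeGrid
    displacement: np.ndarray
    time_s: float = 0.0

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        if self.displacement.shape != (*self.grid.shape, 3):
            raise ValidationError(
                f"displacement shape {self.displacement.shape} != "
                f"{(*self.grid.shape, 3)}"
            )
        if not np.all(np.isfinite(self.displacement)):
            raise ValidationError("displacement field must be finite")

    @classmethod
    def zero(cls, grid: VolumeGrid, time_s: float = 0.0) -> "MotionField":
        return cls(grid, np.zeros((*grid.shape, 3)), time_s)

    @property
    def max_abs_mm(self) -> float:
        return float(np.max(np.abs(self.displacement))) if self.displacement.size else 0.0


def evaluate_motion_field(
    params: MotionParameters,
    grid: VolumeGrid,
    frame_time: float,
    spatial_domain=None,
) -> MotionField:
    """delta(r) = sum_c sigma_c(r) tau_c(t); D(r) = r + delta(r)."""
    tau = params.temporal_profiles(np.array([frame_time]))[:, 0]
    if spatial_domain is None:
        spatial_domain = params.spatial_domain
    Bx, By, Bz = spatial_basis(params.config, grid, domain=spatial_domain)
    disp = np.zeros((*grid.shape, 3))
    for c in range(params.n_components):
        if tau[c] == 0.0:
            continue
        for p in range(3):
            disp[..., p] += tau[c] * expand_spatial(Bx, By, Bz, params.spatial[c, p])
    return MotionField(grid, disp, frame_time)


def motion_jacobian(
    params: MotionParameters, grid: VolumeGrid, frame_time: float
) -> np.ndarray:
    """Displacement-gradient tensor J[..., p, d] = d delta_p / d r_d (mm/mm).

    Computed analytically from the B-spline derivative expansion.
    """
    tau = params.temporal_profiles(np.array([frame_time]))[:, 0]
    bases = [
        spatial_basis(params.config, grid, deriv_axis=d, domain=params.spatial_domain)
        for d in range(3)
    ]
    jac = np.zeros((*grid.shape, 3, 3))
    for c in range(params.n_components):
        if tau[c] == 0.0:
            continue
        for p in range(3):
            for d in range(3):
                Bx, By, Bz = bases[d]
                jac[..., p, d] += tau[c] * expand_spatial(
                    Bx, By, Bz, params.spatial[c, p]
                )
    return jac
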