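"""Synthetic dynamic thorax phantom and noisy cone-beam acquisition simulator.

The phantom is a parametric sum of (optionally axially clipped) ellipsoids
with a sharp lung-liver-style interface: a high-contrast axial step between
a low-attenuation lung region and a homogeneous liver-like region, plus
rib-like dense inclusions.  Structure edges are smoothed over about one
voxel so the voxelization is band-limited for the projector while the
interface stays sharp at the voxel scale.

Respiratory motion is a semi-periodic superior-inferior-dominated
displacement: per breathing cycle the amplitude and period are drawn around
their means (mean period 5 s), and within a cycle the displacement follows
a sin^2 profile.  The motion can be exported either as dense per-frame
fields or as an exact rank-1 instance of the low-rank spline model (useful
for recovery experiments free of model mismatch).

The acquisition protocol mirrors a clinical half-arc CBCT scan: 160 frames,
182 ms apart, covering 180 degrees, 512x512 detector at 0.8 mm pitch and
1536 mm source-detector distance; desk-scale variants shrink the detector
while enlarging the pixel pitch so magnification and FOV are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .geometry import ProjectionSet, ScanGeometry, ValidationError, Volume, VolumeGrid
from .motion import (
    MotionField,
    MotionParameters,
    SplineConfig,
    temporal_basis,
)
from .projector import forward_project
from .warping import pull

__all__ = [
    "Ellipsoid",
    "PhantomSpec",
    "RespiratorySpec",
    "NoiseSpec",
    "RespiratoryMotion",
    "SimulationResult",
    "make_phantom",
    "default_thorax_phantom",
    "make_respiratory_motion",
    "simulate_acquisition",
    "default_protocol",
]


@dataclass(frozen=True)
class Ellipsoid:
    center_mm: Tuple[float, float, float]
    semiaxes_mm: Tuple[float, float, float]
    attenuation: float  # additive, per mm
    clip_z_mm: Tuple[float, float] | None = None  # keep only zmin <= z <= zmax


@dataclass
class PhantomSpec:
    grid: VolumeGrid
    ellipsoids: List[Ellipsoid] = field(default_factory=list)


@dataclass(frozen=True)
class RespiratorySpec:
    """Semi-periodic breathing pattern.

    Amplitude default follows the clinically observed range (about 5-30 mm,
    15 mm on average); mean period 5 s.
    """

    mean_period_s: float = 5.0
    period_jitter_fraction: float = 0.1
    amplitude_mm: float = 15.0
    amplitude_jitter_fraction: float = 0.1
    motion_axis_weights: Tuple[float, float, float] = (0.10, 0.15, -1.0)
    #: "midventilation" centers each cycle's sin^2 profile on zero (the static
    #: phantom then sits in the state a breathing-averaged image gravitates
    #: to); "exhale" keeps the profile in [0, amplitude].
    baseline: str = "midventilation"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_period_s <= 0:
            raise ValidationError("respiratory period must be positive")
        if self.amplitude_mm < 0:
            raise ValidationError("amplitude must be >= 0")
        if self.baseline not in ("midventilation", "exhale"):
            raise ValidationError(f"unknown baseline {self.baseline!r}")


@dataclass(frozen=True)
class NoiseSpec:
    s0: float = 1.0e5
    electronic_variance: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.s0 <= 0:
            raise ValidationError("source intensity must be positive")
        if self.electronic_variance < 0:
            raise ValidationError("electronic variance must be >= 0")


def _smoothstep(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


def make_phantom(spec: PhantomSpec) -> Volume:
    """Additive smooth-edged ellipsoid attenuation map (deterministic)."""
    grid = spec.grid
    X, Y, Z = grid.meshgrid()
    values = np.zeros(grid.shape)
    vox = min(grid.voxel_size_mm)
    for e in spec.ellipsoids:
        rho = np.sqrt(
            ((X - e.center_mm[0]) / e.semiaxes_mm[0]) ** 2
            + ((Y - e.center_mm[1]) / e.semiaxes_mm[1]) ** 2
            + ((Z - e.center_mm[2]) / e.semiaxes_mm[2]) ** 2
        )
        # ~1 voxel wide edge in world units
        w = vox / min(e.semiaxes_mm)
        ind = _smoothstep((1.0 - rho) / w + 0.5)
        if e.clip_z_mm is not None:
            zmin, zmax = e.clip_z_mm
            dz = grid.voxel_size_mm[2]
            ind = ind * _smoothstep((Z - zmin) / dz + 0.5)
            ind = ind * _smoothstep((zmax - Z) / dz + 0.5)
        values += e.attenuation * ind
    if np.any(values < -1e-9):
        raise ValidationError("overlapping negative regions produce negative attenuation")
    return Volume(grid, np.maximum(values, 0.0))


def default_thorax_phantom(grid: VolumeGrid) -> Volume:
    """Thorax-like phantom scaled to the grid extent.

    Soft-tissue body, two low-attenuation lungs ending on a sharp axial
    diaphragm-like interface, a homogeneous liver-like region below it, a
    tumor-like sphere in one lung and rib-like dense inclusions.
    """
    ex, ey, ez = grid.extent_mm
    z_d = -0.05 * ez  # diaphragm plane
    ells = [
        Ellipsoid((0, 0, 0), (0.34 * ex, 0.27 * ey, 0.45 * ez), 0.020),
        Ellipsoid(
            (0.14 * ex, 0, 0.08 * ez),
            (0.11 * ex, 0.14 * ey, 0.25 * ez),
            -0.016,
            clip_z_mm=(z_d, 1e9),
        ),
        Ellipsoid(
            (-0.14 * ex, 0, 0.08 * ez),
            (0.11 * ex, 0.14 * ey, 0.25 * ez),
            -0.016,
            clip_z_mm=(z_d, 1e9),
        ),
        # liver-like homogeneous region under the diaphragm
        Ellipsoid(
            (0.10 * ex, 0.02 * ey, -0.16 * ez),
            (0.20 * ex, 0.18 * ey, 0.14 * ez),
            0.005,
            clip_z_mm=(-1e9, z_d),
        ),
        # tumor-like sphere in the left lung
        Ellipsoid((-0.14 * ex, 0.03 * ey, 0.12 * ez), (0.035 * ex,) * 3, 0.014),
    ]
    for k in range(6):
        ang = np.pi * (0.15 + 0.14 * k)
        ells.append(
            Ellipsoid(
                (0.30 * ex * np.cos(ang), 0.24 * ey * np.sin(ang), 0.10 * ez),
                (0.022 * ex, 0.022 * ey, 0.10 * ez),
                0.022,
            )
        )
    return make_phantom(PhantomSpec(grid, ells))


class RespiratoryMotion:
    """Ground-truth breathing motion: amplitude profile x spatial envelope."""

    def __init__(self, spec: RespiratorySpec, timestamps: np.ndarray):
        timestamps = np.asarray(timestamps, dtype=np.float64)
        if np.any(np.diff(timestamps) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        self.spec = spec
        self.timestamps = timestamps
        rng = np.random.default_rng(spec.rng_seed)
        duration = timestamps[-1] - timestamps[0]
        periods, amplitudes, starts = [], [], []
        t = float(timestamps[0])
        while t <= timestamps[-1] + 1e-9:
            jp = spec.period_jitter_fraction
            ja = spec.amplitude_jitter_fraction
            T = spec.mean_period_s * (1.0 + jp * rng.uniform(-1.0, 1.0))
            A = spec.amplitude_mm * (1.0 + ja * rng.uniform(-1.0, 1.0))
            periods.append(T)
            amplitudes.append(A)
            starts.append(t)
            t += T
        self.cycle_periods = np.array(periods)
        self.cycle_amplitudes = np.array(amplitudes)
        self.cycle_starts = np.array(starts)
        self._duration = duration

    def amplitude_at(self, times: np.ndarray) -> np.ndarray:
        """Signed breathing profile a(t) in mm.

        Within each cycle the profile is amplitude * sin^2(pi * phase); with
        the mid-ventilation baseline the per-cycle mean (amplitude / 2) is
        subtracted, so peaks reach +A/2 and end-exhale dips to -A/2.
        """
        times = np.atleast_1d(np.asarray(times, dtype=np.float64))
        offset = 0.5 if self.spec.baseline == "midventilation" else 0.0
        out = np.zeros_like(times)
        for i, t in enumerate(times):
            k = int(np.searchsorted(self.cycle_starts, t, side="right") - 1)
            k = max(0, min(k, len(self.cycle_starts) - 1))
            phase = (t - self.cycle_starts[k]) / self.cycle_periods[k]
            out[i] = self.cycle_amplitudes[k] * (np.sin(np.pi * phase) ** 2 - offset)
        return out

    def envelope(self, grid: VolumeGrid) -> np.ndarray:
        """Spatial weight in [0, 1]: ~1 below the diaphragm, fading upward."""
        _, _, Z = grid.meshgrid()
        ez = grid.extent_mm[2]
        z_d = -0.05 * ez
        w = 0.10 * ez
        return 1.0 / (1.0 + np.exp((Z - z_d) / w))

    def dense_field(self, grid: VolumeGrid, time_s: float) -> MotionField:
        a = float(self.amplitude_at(np.array([time_s]))[0])
        env = self.envelope(grid)
        weights = np.asarray(self.spec.motion_axis_weights)
        disp = env[..., None] * (a * weights)[None, None, None, :]
        return MotionField(grid, disp, time_s)

    def as_parameters(
        self, spline_config: SplineConfig, grid: VolumeGrid
    ) -> MotionParameters:
        """Exact rank-1 instance of the motion model approximating this motion.

        Spatial coefficients sample the envelope at the control points;
        temporal coefficients are the least-squares spline fit of the
        breathing profile.  The *returned parameters* are then the exact
        ground truth for model-based recovery experiments.
        """
        tdomain = (float(self.timestamps[0]), float(self.timestamps[-1]))
        params = MotionParameters.zeros(
            spline_config, tdomain, n_components=1,
            spatial_domain=MotionParameters.domain_of(grid),
        )
        # control point world coordinates per axis (Greville-like: uniform)
        cp = spline_config.spatial_control_points_per_dim
        env_vals = None
        axes_pts = []
        for axis in range(3):
            c = grid.axis_coordinates(axis)
            axes_pts.append(np.linspace(c[0], c[-1], cp[axis]))
        Xc, Yc, Zc = np.meshgrid(*axes_pts, indexing="ij")
        ez = grid.extent_mm[2]
        z_d = -0.05 * ez
        w = 0.10 * ez
        env_vals = 1.0 / (1.0 + np.exp((Zc - z_d) / w))
        weights = np.asarray(self.spec.motion_axis_weights)
        for p in range(3):
            params.spatial[0, p] = env_vals * weights[p]
        Bt = temporal_basis(spline_config, self.timestamps, tdomain)
        profile = self.amplitude_at(self.timestamps)
        coeffs, *_ = np.linalg.lstsq(Bt, profile, rcond=None)
        params.temporal[0] = coeffs
        return params


def make_respiratory_motion(
    spec: RespiratorySpec, timestamps: np.ndarray
) -> RespiratoryMotion:
    return RespiratoryMotion(spec, timestamps)


@dataclass
class SimulationResult:
    counts: ProjectionSet
    clean_line_integrals: ProjectionSet
    phantom: Volume
    truth_motion: object  # RespiratoryMotion | MotionParameters | None
    noise: NoiseSpec


def _frame_field(motion, grid: VolumeGrid, time_s: float) -> MotionField | None:
    if motion is None:
        return None
    if isinstance(motion, MotionParameters):
        from .motion import evaluate_motion_field

        return evaluate_motion_field(motion, grid, time_s)
    return motion.dense_field(grid, time_s)


def simulate_acquisition(
    phantom: Volume,
    motion,
    geom: ScanGeometry,
    noise: NoiseSpec = NoiseSpec(),
    noise_free: bool = False,
) -> SimulationResult:
    """Dynamic acquisition: deform, project, then apply the counts noise model.

    Per frame t: the phantom is pulled to its motion state, forward
    projected to a clean line integral y_t, and the measured counts are
    Poisson(s0 * exp(-y_t)) + Normal(0, electronic variance), floored at 0.
    With ``noise_free=True`` both noise sources are replaced by their means,
    so counts = s0 * exp(-y_t) exactly.
    """
    grid = phantom.grid
    rng = np.random.default_rng(noise.rng_seed)
    T = geom.n_frames
    clean = np.empty((T, geom.detector_rows, geom.detector_cols))
    counts = np.empty_like(clean)

    precomputed = None
    if isinstance(motion, MotionParameters):
        sigma = motion.spatial_fields(grid)
        tau = motion.temporal_profiles(geom.timestamps_s)
        precomputed = (sigma, tau)

    for t in range(T):
        time_s = float(geom.timestamps_s[t])
        if precomputed is not None:
            sigma, tau = precomputed
            delta = np.tensordot(tau[:, t], sigma, axes=(0, 0))
            fld = MotionField(grid, np.ascontiguousarray(np.moveaxis(delta, 0, -1)), time_s)
        else:
            fld = _frame_field(motion, grid, time_s)
        frame_vol = pull(phantom, fld) if fld is not None else phantom
        y = forward_project(frame_vol, geom, t, check_finite=False)
        clean[t] = y
        mean_counts = noise.s0 * np.exp(-y)
        if noise_free:
            counts[t] = mean_counts
        else:
            c = rng.poisson(mean_counts).astype(np.float64)
            if noise.electronic_variance > 0:
                c += rng.normal(0.0, np.sqrt(noise.electronic_variance), c.shape)
            counts[t] = np.maximum(np.rint(c), 0.0)
    return SimulationResult(
        counts=ProjectionSet(geom, counts, domain="counts"),
        clean_line_integrals=ProjectionSet(geom, clean, domain="line_integral"),
        phantom=phantom,
        truth_motion=motion,
        noise=noise,
    )


def default_protocol(
    detector_rows: int = 512,
    detector_cols: int = 512,
    n_frames: int = 160,
    frame_spacing_s: float = 0.182,
    arc_deg: float = 180.0,
    sdd_mm: float = 1536.0,
    sad_mm: float = 1000.0,
    start_angle_deg: float = 0.0,
) -> ScanGeometry:
    """Half-arc CBCT protocol; desk-scale variants shrink the detector grid.

    The pixel pitch scales as 0.8 mm * 512 / n so that detector coverage
    (hence FOV) and the magnification SDD/SAD are preserved at any scale.
    """
    pitch_v = 0.8 * 512.0 / detector_rows
    pitch_u = 0.8 * 512.0 / detector_cols
    angles = start_angle_deg + arc_deg * np.arange(n_frames) / n_frames
    times = frame_spacing_s * np.arange(n_frames)
    return ScanGeometry(
        source_to_isocenter_mm=sad_mm,
        source_to_detector_mm=sdd_mm,
        detector_rows=detector_rows,
        detector_cols=detector_cols,
        pixel_spacing_mm=(pitch_v, pitch_u),
        angles_deg=angles,
        timestamps_s=times,
    )
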