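"""Cone-beam scan geometry and the basic image/projection containers.

Conventions used throughout the package:

* World coordinates are in millimetres, axes ``(x, y, z)`` with ``z`` the
  rotation (superior-inferior) axis.  The isocenter is the world origin.
* Gantry angle 0 deg puts the source on the +y axis; angles increase
  counter-clockwise when viewed from +z.
* The detector is flat.  Its column axis ``u`` lies in the rotation plane,
  its row axis ``v`` is parallel to +z.
* ``Volume.values`` is indexed ``[ix, iy, iz]``; a voxel's value is the
  attenuation (per mm) at the voxel center.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

__all__ = [
    "ScanGeometry",
    "VolumeGrid",
    "Volume",
    "ProjectionSet",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class ScanGeometry:
    """Circular cone-beam acquisition description.

    Parameters
    ----------
    source_to_isocenter_mm:
        Distance from the X-ray source to the rotation axis (SAD).
    source_to_detector_mm:
        Distance from the source to the flat detector panel (SDD).
    detector_rows, detector_cols:
        Detector grid size; rows run along z, columns along the in-plane
        tangential direction.
    pixel_spacing_mm:
        ``(row_spacing, col_spacing)`` detector pixel pitch in mm.
    angles_deg:
        Gantry angle of every acquired frame.
    timestamps_s:
        Acquisition time of every frame, strictly increasing.
    """

    source_to_isocenter_mm: float
    source_to_detector_mm: float
    detector_rows: int
    detector_cols: int
    pixel_spacing_mm: Tuple[float, float]
    angles_deg: np.ndarray
    timestamps_s: np.ndarray

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles_deg, dtype=np.float64)
        times = np.asarray(self.timestamps_s, dtype=np.float64)
        object.__setattr__(self, "angles_deg", angles)
        object.__setattr__(self, "timestamps_s", times)
        if angles.ndim != 1 or times.ndim != 1 or len(angles) != len(times):
            raise ValidationError(
                "angles_deg and timestamps_s must be 1D and equally long"
            )
        if len(times) == 0:
            raise ValidationError("geometry needs at least one frame")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        if not (0.0 < self.source_to_isocenter_mm < self.source_to_detector_mm):
            raise ValidationError("require 0 < SAD < SDD")
        if self.detector_rows < 1 or self.detector_cols < 1:
            raise ValidationError("detector grid must be at least 1x1")
        if min(self.pixel_spacing_mm) <= 0:
            raise ValidationError("pixel spacing must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.angles_deg)

    @property
    def magnification(self) -> float:
        return self.source_to_detector_mm / self.source_to_isocenter_mm

    def source_position(self, frame: int) -> np.ndarray:
        """World position of the source for one frame."""
        theta = np.deg2rad(self.angles_deg[frame])
        sad = self.source_to_isocenter_mm
        return np.array([-sad * np.sin(theta), sad * np.cos(theta), 0.0])

    def detector_frame(self, frame: int):
        """Return (detector center, u axis, v axis) in world coordinates."""
        theta = np.deg2rad(self.angles_deg[frame])
        ray = np.array([np.sin(theta), -np.cos(theta), 0.0])  # source -> isocenter
        center = self.source_position(frame) + self.source_to_detector_mm * ray
        u_axis = np.array([np.cos(theta), np.sin(theta), 0.0])
        v_axis = np.array([0.0, 0.0, 1.0])
        return center, u_axis, v_axis

    def subset(self, frames) -> "ScanGeometry":
        """Geometry restricted to a subset of frames (e.g. for previews)."""
        return replace(
            self,
            angles_deg=self.angles_deg[frames],
            timestamps_s=self.timestamps_s[frames],
        )


@dataclass(frozen=True)
class VolumeGrid:
    """Uniform 3D voxel grid in world (mm) coordinates."""

    shape: Tuple[int, int, int]
    voxel_size_mm: Tuple[float, float, float]
    origin_mm: Tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if any(int(n) < 1 for n in self.shape):
            raise ValidationError("grid shape entries must be >= 1")
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ValidationError("voxel sizes must be positive")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(
            self, "voxel_size_mm", tuple(float(s) for s in self.voxel_size_mm)
        )
        if self.origin_mm is None:
            # grid centered on the isocenter
            origin = tuple(
                -0.5 * (n - 1) * s for n, s in zip(self.shape, self.voxel_size_mm)
            )
        else:
            origin = tuple(float(o) for o in self.origin_mm)
        object.__setattr__(self, "origin_mm", origin)

    @classmethod
    def isotropic(cls, n: int, voxel_size_mm: float) -> "VolumeGrid":
        return cls((n, n, n), (voxel_size_mm,) * 3)

    @property
    def extent_mm(self) -> Tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.voxel_size_mm))

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin_mm[axis] + self.voxel_size_mm[axis] * np.arange(n)

    def meshgrid(self):
        """World coordinates of all voxel centers, shape (nx, ny, nz) each."""
        ax = [self.axis_coordinates(a) for a in range(3)]
        return np.meshgrid(*ax, indexing="ij")

    def padded(self, margin_fraction: float) -> "VolumeGrid":
        """Grid extended transversally (x, y) by a fraction per side."""
        pad = [
            int(np.ceil(margin_fraction * self.shape[0])),
            int(np.ceil(margin_fraction * self.shape[1])),
            0,
        ]
        shape = tuple(n + 2 * p for n, p in zip(self.shape, pad))
        origin = tuple(
            o - p * s for o, p, s in zip(self.origin_mm, pad, self.voxel_size_mm)
        )
        return VolumeGrid(shape, self.voxel_size_mm, origin)


@dataclass
class Volume:
    """Scalar attenuation image (per mm) on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValidationError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @classmethod
    def zeros(cls, grid: VolumeGrid) -> "Volume":
        return cls(grid, np.zeros(grid.shape))

    def require_finite(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("volume contains non-finite values")

    def copy(self) -> "Volume":
        return Volume(self.grid, self.values.copy(), dict(self.meta))


PROJECTION_DOMAINS = ("counts", "line_integral")


@dataclass
class ProjectionSet:
    """Stack of per-frame 2D detector images.

    ``domain`` is ``"counts"`` (raw photon counts) or ``"line_integral"``
    (negative log of normalized counts, i.e. attenuation line integrals).
    """

    geometry: ScanGeometry
    values: np.ndarray
    domain: str = "line_integral"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = (
            self.geometry.n_frames,
            self.geometry.detector_rows,
            self.geometry.detector_cols,
        )
        if self.values.shape != expected:
            raise ValidationError(
                f"projection stack shape {self.values.shape} != {expected}"
            )
        if self.domain not in PROJECTION_DOMAINS:
            raise ValidationError(f"unknown projection domain {self.domain!r}")
        if self.domain == "counts" and np.any(self.values < 0):
            raise ValidationError("counts-domain projections must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.geometry.n_frames

    def copy(self) -> "ProjectionSet":
        return ProjectionSet(self.geometry, self.values.copy(), self.domain)
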