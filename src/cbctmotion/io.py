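"""Readers/writers and validated run configuration.

Volumes are stored as MetaImage (.mha) or NIfTI (.nii/.nii.gz) through
SimpleITK with spacing and origin preserved; projection stacks as HDF5
(canonical, geometry embedded) or multi-page TIFF with a sidecar geometry
JSON; motion parameters as HDF5.  Run configuration is YAML validated
against a strict schema (unknown keys are rejected) with presets mirroring
the in-silico / phantom / clinical experiment settings.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple, Union

import h5py
import numpy as np
import SimpleITK as sitk
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .estimation import EstimationConfig
from .framework import MotusConfig
from .geometry import ProjectionSet, ScanGeometry, ValidationError, Volume, VolumeGrid
from .motion import MotionParameters, SplineConfig
from .reconstruction import SIRTConfig
from .regularization import RegularizerConfig

__all__ = [
    "read_volume",
    "write_volume",
    "read_projections",
    "write_projections",
    "read_geometry",
    "write_geometry",
    "read_motion_parameters",
    "write_motion_parameters",
    "read_displacement_field",
    "write_displacement_field",
    "load_config",
    "PRESETS",
]

_VOLUME_EXTS = (".mha", ".mhd", ".nii", ".nii.gz")


def _check_volume_ext(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(e) for e in _VOLUME_EXTS):
        raise ValidationError(f"unknown volume format for {path.name!r}")


def write_volume(path, vol: Volume) -> None:
    path = Path(path)
    _check_volume_ext(path)
    # SimpleITK's numpy view is (z, y, x); our storage is (x, y, z)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values.T))
    img.SetSpacing(tuple(float(s) for s in vol.grid.voxel_size_mm))
    img.SetOrigin(tuple(float(o) for o in vol.grid.origin_mm))
    sitk.WriteImage(img, str(path))


def read_volume(path) -> Volume:
    path = Path(path)
    _check_volume_ext(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise ValidationError(f"cannot read volume {path.name!r}: {exc}") from exc
    values = sitk.GetArrayFromImage(img).T
    grid = VolumeGrid(values.shape, tuple(img.GetSpacing()), tuple(img.GetOrigin()))
    return Volume(grid, np.asarray(values, dtype=np.float64))


def write_displacement_field(path, field) -> None:
    """Store a dense displacement field as a 3-component vector image (mm)."""
    path = Path(path)
    _check_volume_ext(path)
    # component-last (z, y, x, 3) view for SimpleITK's vector pixel type
    arr = np.ascontiguousarray(np.transpose(field.displacement, (2, 1, 0, 3)))
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(tuple(float(s) for s in field.grid.voxel_size_mm))
    img.SetOrigin(tuple(float(o) for o in field.grid.origin_mm))
    sitk.WriteImage(img, str(path))


def read_displacement_field(path, time_s: float = 0.0):
    """Read a vector displacement image back into a MotionField."""
    from .motion import MotionField

    path = Path(path)
    _check_volume_ext(path)
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValidationError(f"{path.name!r} is not a 3-component vector image")
    disp = np.transpose(arr, (2, 1, 0, 3)).astype(np.float64)
    grid = VolumeGrid(disp.shape[:3], tuple(img.GetSpacing()), tuple(img.GetOrigin()))
    return MotionField(grid, disp, time_s)


def _geometry_to_dict(geom: ScanGeometry) -> dict:
    return {
        "source_to_isocenter_mm": geom.source_to_isocenter_mm,
        "source_to_detector_mm": geom.source_to_detector_mm,
        "detector_rows": geom.detector_rows,
        "detector_cols": geom.detector_cols,
        "pixel_spacing_mm": list(geom.pixel_spacing_mm),
        "angles_deg": geom.angles_deg.tolist(),
        "timestamps_s": geom.timestamps_s.tolist(),
    }


def _geometry_from_dict(d: dict) -> ScanGeometry:
    required = {
        "source_to_isocenter_mm",
        "source_to_detector_mm",
        "detector_rows",
        "detector_cols",
        "pixel_spacing_mm",
        "angles_deg",
        "timestamps_s",
    }
    missing = required - set(d)
    if missing:
        raise ValidationError(f"geometry document missing keys: {sorted(missing)}")
    return ScanGeometry(
        source_to_isocenter_mm=float(d["source_to_isocenter_mm"]),
        source_to_detector_mm=float(d["source_to_detector_mm"]),
        detector_rows=int(d["detector_rows"]),
        detector_cols=int(d["detector_cols"]),
        pixel_spacing_mm=tuple(d["pixel_spacing_mm"]),
        angles_deg=np.asarray(d["angles_deg"], dtype=np.float64),
        timestamps_s=np.asarray(d["timestamps_s"], dtype=np.float64),
    )


def write_geometry(path, geom: ScanGeometry) -> None:
    path = Path(path)
    doc = _geometry_to_dict(geom)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc))
    else:
        path.write_text(json.dumps(doc, indent=1))


def read_geometry(path) -> ScanGeometry:
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return _geometry_from_dict(doc)


def write_projections(path, projections: ProjectionSet, geometry_path=None) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("projections", data=projections.values)
            ds.attrs["domain"] = projections.domain
            f.attrs["geometry_json"] = json.dumps(_geometry_to_dict(projections.geometry))
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, projections.values.astype(np.float32))
        gpath = Path(geometry_path) if geometry_path else path.with_suffix(".geometry.json")
        write_geometry(gpath, projections.geometry)
    else:
        raise ValidationError(f"unknown projection format for {path.name!r}")


def read_projections(path, geometry_path=None, domain: str | None = None) -> ProjectionSet:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            values = np.asarray(f["projections"])
            file_domain = f["projections"].attrs.get("domain", "line_integral")
            geom = _geometry_from_dict(json.loads(f.attrs["geometry_json"]))
        return ProjectionSet(geom, values, domain or str(file_domain))
    if path.suffix in (".tif", ".tiff"):
        gpath = Path(geometry_path) if geometry_path else path.with_suffix(".geometry.json")
        geom = read_geometry(gpath)
        values = np.asarray(tifffile.imread(path), dtype=np.float64)
        return ProjectionSet(geom, values, domain or "line_integral")
    raise ValidationError(f"unknown projection format for {path.name!r}")


def write_motion_parameters(path, params: MotionParameters) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("spatial", data=params.spatial)
        f.create_dataset("temporal", data=params.temporal)
        f.attrs["spatial_control_points_per_dim"] = params.config.spatial_control_points_per_dim
        f.attrs["temporal_control_point_rate"] = params.config.temporal_control_point_rate
        f.attrs["temporal_domain"] = params.temporal_domain
        if params.spatial_domain is not None:
            f.attrs["spatial_domain"] = np.asarray(params.spatial_domain)


def read_motion_parameters(path) -> MotionParameters:
    with h5py.File(path, "r") as f:
        cfg = SplineConfig(
            tuple(int(n) for n in f.attrs["spatial_control_points_per_dim"]),
            float(f.attrs["temporal_control_point_rate"]),
        )
        sdom = None
        if "spatial_domain" in f.attrs:
            sdom = tuple(tuple(float(v) for v in row) for row in f.attrs["spatial_domain"])
        return MotionParameters(
            cfg,
            np.asarray(f["spatial"]),
            np.asarray(f["temporal"]),
            tuple(float(t) for t in f.attrs["temporal_domain"]),
            sdom,
        )


# --------------------------------------------------------------------------
# configuration schema


class _SplineModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    spatial_control_points_per_dim: Union[int, Tuple[int, int, int]] = 32
    temporal_control_point_rate: float = Field(2.0, gt=0)


class _EstimationModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    learning_rate: float = Field(0.1, gt=0)
    n_epochs: int = Field(100, ge=1)
    init_scale: float = Field(0.01, ge=0)


class _RegularizerModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    weight: float = Field(1.0e-6, ge=0)
    gradient_mode: str = "analytic_bspline"
    convention: str = "displacement"


class _SIRTModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_iterations: int = Field(200, ge=1)
    nonnegativity: bool = True
    extended_domain_margin: float = Field(0.25, ge=0)


class _MotusModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_alternations: int = Field(50, ge=0)
    convergence_rel_tol: float = Field(1.0e-3, gt=0)
    n_components: int = Field(1, ge=1)
    master_seed: int = 0
    spline: _SplineModel = _SplineModel()
    estimation: _EstimationModel = _EstimationModel()
    regularizer: _RegularizerModel = _RegularizerModel()
    sirt: _SIRTModel = _SIRTModel()


#: experiment presets: half-arc protocol settings for the three study arms
PRESETS = {
    "insilico": {},
    "phantom": {"spline": {"spatial_control_points_per_dim": 7}},
    "clinical": {
        "n_components": 3,
        "max_alternations": 20,
        "spline": {"temporal_control_point_rate": 3.0},
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, preset: str = "insilico", overrides: dict | None = None) -> MotusConfig:
    """Build a :class:`MotusConfig` from a preset + optional YAML + overrides.

    Unknown or invalid keys raise with the offending key in the message.
    An empty/absent file yields the in-silico defaults.
    """
    if preset not in PRESETS:
        raise ValidationError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    doc: dict = dict(PRESETS[preset])
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValidationError("config file must contain a YAML mapping")
        doc = _merge(doc, loaded)
    if overrides:
        doc = _merge(doc, overrides)
    model = _MotusModel.model_validate(doc)
    return MotusConfig(
        max_alternations=model.max_alternations,
        convergence_rel_tol=model.convergence_rel_tol,
        n_components=model.n_components,
        master_seed=model.master_seed,
        spline=SplineConfig(
            model.spline.spatial_control_points_per_dim,
            model.spline.temporal_control_point_rate,
        ),
        estimation=EstimationConfig(
            learning_rate=model.estimation.learning_rate,
            n_epochs=model.estimation.n_epochs,
            init_scale=model.estimation.init_scale,
            rng_seed=model.master_seed,
        ),
        regularizer=RegularizerConfig(
            weight=model.regularizer.weight,
            gradient_mode=model.regularizer.gradient_mode,
            convention=model.regularizer.convention,
        ),
        sirt=SIRTConfig(
            n_iterations=model.sirt.n_iterations,
            nonnegativity=model.sirt.nonnegativity,
            extended_domain_margin=model.sirt.extended_domain_margin,
        ),
    )
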