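"""Quantitative image and motion metrics.

* ``ssim_volume`` — structural similarity with a Gaussian window, averaged
  over a field-of-view mask.
* ``esf_width`` — width of an error-function edge-spread model fitted to a
  line profile; 1 / width is the sharpness (spatial resolution) proxy.
* ``motion_rmse`` — per-axis RMSE between displacement-versus-time profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import ndtr
from skimage.metrics import structural_similarity

from .geometry import ValidationError, Volume

__all__ = ["ssim_volume", "esf_width", "ESFFit", "motion_rmse"]


def ssim_volume(a: Volume, b: Volume, fov_mask: np.ndarray | None = None) -> float:
    """Mean SSIM over the FOV mask (Gaussian window, standard constants)."""
    if a.grid.shape != b.grid.shape:
        raise ValidationError("volumes must share a grid for SSIM")
    data_range = float(
        max(a.values.max(), b.values.max()) - min(a.values.min(), b.values.min())
    )
    if data_range == 0:
        return 1.0
    mssim, ssim_map = structural_similarity(
        a.values,
        b.values,
        data_range=data_range,
        gaussian_weights=True,
        sigma=1.5,
        use_sample_covariance=False,
        full=True,
    )
    if fov_mask is None:
        return float(mssim)
    fov_mask = np.asarray(fov_mask, dtype=bool)
    if fov_mask.shape != a.grid.shape:
        raise ValidationError("FOV mask shape does not match the volume grid")
    if not fov_mask.any():
        raise ValidationError("FOV mask is empty")
    return float(ssim_map[fov_mask].mean())


@dataclass
class ESFFit:
    width_mm: float
    center_mm: float
    amplitude: float
    offset: float
    converged: bool

    @property
    def sharpness_per_mm(self) -> float:
        return 1.0 / self.width_mm if self.width_mm > 0 else np.inf


def esf_width(profile: np.ndarray, spacing_mm: float = 1.0) -> ESFFit:
    """Fit offset + amplitude * Phi((x - x0) / w) to a 1D edge profile.

    Phi is the standard normal CDF, i.e. the edge-spread function of a
    Gaussian line-spread with standard deviation w.  For a step edge
    blurred by a Gaussian of sigma, the fitted w equals sigma.
    """
    profile = np.asarray(profile, dtype=np.float64)
    if profile.ndim != 1 or profile.size < 5:
        raise ValidationError("profile must be 1D with at least 5 samples")
    x = spacing_mm * np.arange(profile.size)

    def model(xx, offset, amplitude, x0, w):
        return offset + amplitude * ndtr((xx - x0) / abs(w))

    lo, hi = float(profile.min()), float(profile.max())
    rising = profile[-1] >= profile[0]
    p0 = [
        lo if rising else hi,
        (hi - lo) if rising else (lo - hi),
        x[len(x) // 2],
        max(spacing_mm, 0.05 * (x[-1] - x[0])),
    ]
    try:
        popt, _ = curve_fit(model, x, profile, p0=p0, maxfev=20000)
    except (RuntimeError, ValueError):
        return ESFFit(np.nan, np.nan, np.nan, np.nan, converged=False)
    offset, amplitude, x0, w = popt
    return ESFFit(abs(float(w)), float(x0), float(amplitude), float(offset), True)


def motion_rmse(estimated: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Per-axis RMSE (mm) between (n_frames, 3) displacement profiles."""
    estimated = np.asarray(estimated, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if estimated.shape != truth.shape:
        raise ValidationError("profiles must have identical shapes")
    diff = estimated - truth
    return np.sqrt(np.mean(diff * diff, axis=0))
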