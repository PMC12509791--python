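"""Spatial smoothness penalty on the motion-field Jacobian.

The penalty is the squared L2 (Dirichlet) norm of all nine displacement
gradients, summed over voxels and frames:

    R = sum_t sum_{p,d} || d delta_t^p / d r_d ||^2

Penalizing the gradients of the *displacement* delta (default) makes the
penalty zero for rigid translations, which is the behaviour a motion prior
should have; penalizing the gradients of the full mapping D = r + delta is
also exposed (``convention="mapping"``) but is minimized by a degenerate
collapse of the field and is kept only for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ValidationError, VolumeGrid
from .motion import (
    MotionField,
    MotionParameters,
    contract_spatial,
    expand_spatial,
    motion_jacobian,
    spatial_basis,
    temporal_basis,
)

__all__ = ["RegularizerConfig", "jacobian_penalty", "penalty_value_and_grad"]


@dataclass(frozen=True)
class RegularizerConfig:
    weight: float = 1.0e-6
    gradient_mode: str = "analytic_bspline"  # or "finite_difference"
    convention: str = "displacement"  # or "mapping"

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValidationError("regularization weight must be >= 0")
        if self.gradient_mode not in ("analytic_bspline", "finite_difference"):
            raise ValidationError(f"unknown gradient_mode {self.gradient_mode!r}")
        if self.convention not in ("displacement", "mapping"):
            raise ValidationError(f"unknown convention {self.convention!r}")


def _field_penalty_fd(field: MotionField, convention: str) -> float:
    """Finite-difference Dirichlet energy of one dense displacement field."""
    total = 0.0
    spacing = field.grid.voxel_size_mm
    for p in range(3):
        grads = np.gradient(field.displacement[..., p], *spacing)
        for d, g in enumerate(grads):
            if convention == "mapping" and d == p:
                g = g + 1.0
            total += float(np.sum(g * g))
    return total


def jacobian_penalty(
    field_or_params,
    grid: VolumeGrid | None = None,
    frame_times=None,
    config: RegularizerConfig = RegularizerConfig(),
) -> float:
    """R summed over the given frames (or over one dense field).

    Accepts either a dense :class:`MotionField` (evaluated with finite
    differences) or :class:`MotionParameters` plus ``grid`` and
    ``frame_times`` (evaluated per ``config.gradient_mode``).
    """
    if isinstance(field_or_params, MotionField):
        return _field_penalty_fd(field_or_params, config.convention)
    params: MotionParameters = field_or_params
    if grid is None or frame_times is None:
        raise ValidationError("grid and frame_times are required for parameters")
    frame_times = np.atleast_1d(np.asarray(frame_times, dtype=np.float64))
    if config.gradient_mode == "finite_difference":
        from .motion import evaluate_motion_field

        return sum(
            _field_penalty_fd(evaluate_motion_field(params, grid, t), config.convention)
            for t in frame_times
        )
    value, _, _ = penalty_value_and_grad(params, grid, frame_times, config.convention)
    return value


def penalty_value_and_grad(
    params: MotionParameters,
    grid: VolumeGrid,
    timestamps: np.ndarray,
    convention: str = "displacement",
):
    """Analytic penalty value and its gradients w.r.t. the coefficients.

    Returns ``(value, grad_spatial, grad_temporal)`` with gradients shaped
    like ``params.spatial`` / ``params.temporal``.  Uses the low-rank
    structure: the sum over frames enters only through the Gram matrix of
    the temporal profiles, so the spatial derivative fields are built once.
    """
    timestamps = np.atleast_1d(np.asarray(timestamps, dtype=np.float64))
    nc = params.n_components
    Bt = temporal_basis(params.config, timestamps, params.temporal_domain)
    tau = params.temporal @ Bt.T  # (nc, T)
    gram = tau @ tau.T  # (nc, nc)

    deriv_bases = [
        spatial_basis(params.config, grid, deriv_axis=d, domain=params.spatial_domain)
        for d in range(3)
    ]
    # dsig[c][p][d]: derivative field of component c, displacement axis p,
    # spatial direction d
    dsig = np.empty((nc, 3, 3, *grid.shape))
    for c in range(nc):
        for p in range(3):
            for d in range(3):
                Bx, By, Bz = deriv_bases[d]
                dsig[c, p, d] = expand_spatial(Bx, By, Bz, params.spatial[c, p])

    # M[c, c'] = sum_{p,d} <dsig_c, dsig_c'>
    flat = dsig.reshape(nc, -1)
    M = flat @ flat.T
    value = float(np.sum(gram * M))

    grad_spatial = np.zeros_like(params.spatial)
    for c in range(nc):
        for p in range(3):
            # field-space gradient: 2 * sum_c' G[c,c'] dsig[c', p, d]
            for d in range(3):
                Bx, By, Bz = deriv_bases[d]
                fld = np.tensordot(2.0 * gram[c], dsig[:, p, d], axes=(0, 0))
                grad_spatial[c, p] += contract_spatial(Bx, By, Bz, fld)
    # dR/dtau[c, t] = 2 * sum_c' tau[c', t] M[c, c']; chain through Bt
    dtau = 2.0 * (M @ tau)  # (nc, T)
    grad_temporal = dtau @ Bt

    if convention == "mapping":
        nvox = int(np.prod(grid.shape))
        T = len(timestamps)
        trace_fields = np.empty((nc, *grid.shape))
        for c in range(nc):
            tr = np.zeros(grid.shape)
            for p in range(3):
                tr += dsig[c, p, p]
            trace_fields[c] = tr
        tau_sum = tau.sum(axis=1)  # (nc,)
        value += 2.0 * float(tau_sum @ trace_fields.reshape(nc, -1).sum(axis=1))
        value += 3.0 * T * nvox
        for c in range(nc):
            for p in range(3):
                Bx, By, Bz = deriv_bases[p]
                grad_spatial[c, p] += 2.0 * tau_sum[c] * contract_spatial(
                    Bx, By, Bz, np.ones(grid.shape)
                )
        tr_sums = trace_fields.reshape(nc, -1).sum(axis=1)
        grad_temporal += 2.0 * tr_sums[:, None] * Bt.sum(axis=0)[None, :]

    return value, grad_spatial, grad_temporal


def jacobian_penalty_field_analytic(
    params: MotionParameters, grid: VolumeGrid, frame_time: float
) -> float:
    """Single-frame penalty from the analytic Jacobian (reference path)."""
    jac = motion_jacobian(params, grid, frame_time)
    return float(np.sum(jac * jac))
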