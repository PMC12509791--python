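"""Outer alternation: motion estimation <-> motion-compensated reconstruction.

Starting from a motion-corrupted (uncompensated) SIRT reconstruction as the
reference image, the framework alternates between estimating the motion
that maps the reference to every projection frame and re-reconstructing the
reference with that motion compensated.  The per-alternation final
estimation loss is tracked; the loop stops when it stops improving (relative
improvement below tolerance, or an increase) and the best-loss alternation's
image and motion are returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List

import numpy as np

from .estimation import EstimationConfig, estimate_motion
from .geometry import ProjectionSet, ScanGeometry, ValidationError, Volume, VolumeGrid
from .motion import MotionParameters, SplineConfig
from .projector import estimate_source_intensity, log_transform
from .reconstruction import SIRTConfig, motion_corrupted_reconstruct, sirt_reconstruct
from .regularization import RegularizerConfig

__all__ = ["MotusConfig", "MotusResult", "run_motus", "detect_convergence"]


@dataclass(frozen=True)
class MotusConfig:
    max_alternations: int = 50
    convergence_rel_tol: float = 1.0e-3
    n_components: int = 1
    spline: SplineConfig = SplineConfig()
    estimation: EstimationConfig = EstimationConfig()
    regularizer: RegularizerConfig = RegularizerConfig()
    sirt: SIRTConfig = SIRTConfig()
    master_seed: int = 0
    fresh_init_per_alternation: bool = True

    def __post_init__(self) -> None:
        if self.max_alternations < 0:
            raise ValidationError("max_alternations must be >= 0")


@dataclass
class MotusResult:
    corrected_image: Volume
    motion: MotionParameters
    alternation_losses: np.ndarray
    converged_at: int
    corrupted_image: Volume
    estimation_traces: List[np.ndarray] = field(default_factory=list)


def detect_convergence(loss_history, rel_tol: float = 1.0e-3):
    """(converged, index): stop when the loss increases or barely improves.

    The index is the argmin of the history — the state worth keeping.
    """
    history = np.asarray(loss_history, dtype=np.float64)
    best_index = int(np.argmin(history)) if history.size else 0
    if history.size < 2:
        return False, best_index
    for i in range(1, history.size):
        if history[i] > history[i - 1]:
            return True, best_index
        denom = abs(history[i - 1])
        improvement = (history[i - 1] - history[i]) / denom if denom > 0 else 0.0
        if improvement < rel_tol:
            return True, best_index
    return False, best_index


def run_motus(
    projections: ProjectionSet,
    geom: ScanGeometry,
    grid: VolumeGrid,
    config: MotusConfig = MotusConfig(),
    s0: float | None = None,
    background_roi=None,
    callback=None,
) -> MotusResult:
    """Full gate-less motion-corrected reconstruction.

    ``projections`` may be counts (log-transformed internally, estimating
    the source intensity from a background ROI if ``s0`` is not given) or
    line integrals.  ``grid`` is the FOV reconstruction grid; iterations run
    on the transversally extended domain per the SIRT configuration.
    """
    if projections.domain == "counts":
        if s0 is None:
            if background_roi is None:
                background_roi = (
                    slice(0, max(1, geom.detector_rows // 16)),
                    slice(0, max(1, geom.detector_cols // 16)),
                )
            s0 = estimate_source_intensity(projections, background_roi)
        y = log_transform(projections, s0)
    else:
        y = projections

    corrupted = motion_corrupted_reconstruct(y, geom, grid, config.sirt)
    tdomain = (float(geom.timestamps_s[0]), float(geom.timestamps_s[-1]))
    identity = MotionParameters.zeros(config.spline, tdomain, config.n_components)

    if config.max_alternations == 0:
        return MotusResult(
            corrected_image=corrupted,
            motion=identity,
            alternation_losses=np.array([]),
            converged_at=0,
            corrupted_image=corrupted,
        )

    reference = corrupted
    losses: list[float] = []
    traces: list[np.ndarray] = []
    best = None  # (loss, params, image)
    n_increases = 0
    for a in range(config.max_alternations):
        seed = (config.master_seed + a + 1) % (2**31)
        est_cfg = EstimationConfig(
            learning_rate=config.estimation.learning_rate,
            n_epochs=config.estimation.n_epochs,
            init_scale=config.estimation.init_scale,
            rng_seed=seed if config.fresh_init_per_alternation else config.master_seed,
            beta1=config.estimation.beta1,
            beta2=config.estimation.beta2,
            eps=config.estimation.eps,
        )
        est = estimate_motion(
            reference,
            geom,
            y,
            spline_config=config.spline,
            config=est_cfg,
            reg=config.regularizer,
            n_components=config.n_components,
        )
        losses.append(est.final_loss)
        traces.append(est.loss_trace)
        corrected = sirt_reconstruct(
            y, geom, grid, motion=est.params, config=config.sirt
        )
        if best is None or est.final_loss < best[0]:
            best = (est.final_loss, est.params, corrected)
        if callback is not None:
            callback(a, est.final_loss)
        # next alternation re-estimates against the improved reference
        reference = corrected
        if len(losses) >= 2 and losses[-1] > losses[-2] * (1 + config.convergence_rel_tol):
            n_increases += 1
            if n_increases >= 3:
                warnings.warn(
                    "alternation loss increased for 3 consecutive alternations; "
                    "stopping early and returning the best state"
                )
                break
        else:
            n_increases = 0
        converged, _ = detect_convergence(losses, config.convergence_rel_tol)
        if converged:
            break

    _, best_index = detect_convergence(losses, config.convergence_rel_tol)
    return MotusResult(
        corrected_image=best[2],
        motion=best[1],
        alternation_losses=np.asarray(losses),
        converged_at=best_index,
        corrupted_image=corrupted,
        estimation_traces=traces,
    )
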