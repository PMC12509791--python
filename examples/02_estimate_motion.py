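"""Estimate time-resolved motion directly in projection space.

Uses the motion-field validation design: the true (static) phantom serves
as the reference image, so the recovered displacement profile can be
compared against the known ground truth at a high-contrast voxel.
"""

import numpy as np

import cbctmotion as cm
from cbctmotion.estimation import EstimationConfig, estimate_motion
from cbctmotion.evaluation import motion_rmse
from cbctmotion.phantom import (
    RespiratorySpec,
    default_protocol,
    default_thorax_phantom,
    make_respiratory_motion,
    simulate_acquisition,
)
from cbctmotion.regularization import RegularizerConfig

grid = cm.VolumeGrid.isotropic(32, 8.0)
geom = default_protocol(detector_rows=32, detector_cols=32, n_frames=160)
phantom = default_thorax_phantom(grid)

spec = RespiratorySpec(amplitude_mm=10.0, period_jitter_fraction=0.0,
                       amplitude_jitter_fraction=0.0, baseline="exhale", rng_seed=0)
scfg = cm.SplineConfig((8, 8, 8), 2.0)
truth = make_respiratory_motion(spec, geom.timestamps_s).as_parameters(scfg, grid)
sim = simulate_acquisition(phantom, truth, geom, noise_free=True)
y = cm.log_transform(sim.counts, 1e5)

result = estimate_motion(
    phantom, geom, y, scfg,
    EstimationConfig(n_epochs=60, rng_seed=0),
    RegularizerConfig(weight=1e-6),
)
print(f"loss: {result.loss_trace[0]:.1f} -> {result.final_loss:.3f} over {len(result.loss_trace)} epochs")

# displacement-vs-time at a diaphragm-interface voxel
iz = int(round((-0.05 * grid.extent_mm[2] - grid.origin_mm[2]) / grid.voxel_size_mm[2]))
voxel = (19, 16, iz)
ts = geom.timestamps_s


def profile(params):
    sig = params.spatial_fields(grid)
    tau = params.temporal_profiles(ts)
    return np.stack([np.tensordot(tau[:, t], sig, axes=(0, 0))[:, voxel[0], voxel[1], voxel[2]]
                     for t in range(len(ts))])


rmse = motion_rmse(profile(result.params), profile(truth))
print(f"per-axis RMSE vs ground truth at the tracked voxel: "
      f"x {rmse[0]:.2f} mm, y {rmse[1]:.2f} mm, z {rmse[2]:.2f} mm (voxel = 8 mm)")
# Sub-voxel RMSE on the dominant (z) axis means the 182 ms-resolved
# breathing trace was recovered from single-angle projections.
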