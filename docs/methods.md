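# Methods

## Problem and model

Cone-beam CT acquires one 2D projection per gantry angle over tens of
seconds, so respiratory (and other) motion blurs the reconstruction.
Gating discards the assumption-free part of the problem by sorting frames
into phases; this package instead estimates a *time-resolved* non-rigid
motion model per projection frame and compensates for it inside an
iterative reconstruction, with no periodicity assumption.

The signal model is mono-energetic Beer–Lambert attenuation: detector
counts `s_t = s0 exp(-y_t)` with line integrals `y_t = A_t x_t`, where
`A_t` is the per-frame cone-beam system matrix and `x_t` the attenuation
volume at frame `t`. Taking the negative logarithm of normalized counts
makes the model linear. The dynamic volume is tied to a single reference
image `x0` by a displacement field:

    x_t(r) = x0(r + delta_t(r)),    y_t = A_t pull(x0, delta_t).

**Low-rank spline motion model.** The displacement is a sum of
`N_comp` separable components, each the product of a spatial vector field
(tensor-product cubic B-splines, coefficients in mm) and a scalar temporal
profile (1D cubic B-spline, unitless):

    delta_t(r) = sum_c sigma_c(r) * tau_c(t).

Both bases use uniformly spaced, clamped knots spanning the reconstruction
domain and the scan duration exactly. The rank-1 product carries a gauge
freedom (`(a*sigma)(tau/a)` is the same motion); we leave the factors
unnormalized — only the product is ever consumed. Temporal knot density is
expressed as control points per second of scan (default 2.0 /s, i.e. 58
spline segments over a 29 s scan, 61 coefficients).

**Estimation.** Motion coefficients minimize the projection-domain loss

    L(c) = sum_t || A_t pull(x0, delta_t(c)) - y_t ||^2 + lambda * R(c)

by NAdam (learning rate 0.1, 100 epochs at full scale, full-batch over all
frames) from a small uniform random initialization (scale 0.01). The exact
zero vector is a stationary point of the bilinear model, so the random
start is what breaks the spatial/temporal symmetry. Gradients are exact
analytic derivatives of the discrete forward model: the residual is
backprojected with the projector's exact adjoint, multiplied by the exact
gradient of the trilinear interpolant at the warped sample points, and
contracted against the spline bases. Because the low-rank structure makes
the spatial contraction frame-independent, the per-frame work reduces to
one pull/project/backproject sweep; the basis contraction happens once per
epoch.

**Regularization.** `R` is the squared L2 (Dirichlet) norm of all nine
displacement-gradient components, summed over voxels and frames, with
weight `lambda = 1e-6`. We penalize the gradients of the *displacement*
`delta` rather than of the full mapping `r + delta`: the latter is
minimized by a degenerate collapse of the field and is not translation
invariant; both conventions are exposed via a flag, displacement is the
default. Whether the functional should be summed per frame or pooled is
ambiguous on its face; we sum per frame, which the low-rank structure
reduces to a temporal Gram matrix times spatial inner products.

**Motion-compensated SIRT.** Reconstruction iterates

    x <- max(0, x + C * sum_t Winv_t{ A_t^T R_t (y_t - A_t W_t{x}) })

with `R_t = 1/(A_t 1)` and `C = 1/(sum_t A_t^T 1)` elementwise, floored at
1e-6 of the median positive entry before inversion (rays that miss the
volume and voxels no ray touches contribute nothing anyway). `W_t` is the
trilinear pull warp; the exact inverse displacement generally does not
exist, so `Winv_t` is the normalized push: the exact adjoint splat divided
by the splat of a ones-image, voxels receiving no mass set to 0 (air).
Iterations start from zero and run on a reconstruction domain extended
transversally by 25% per side, because the object commonly extends beyond
the field of view. 200 iterations at full scale.

**Alternation.** Starting from an uncompensated ("motion-corrupted") SIRT
reconstruction as reference, the framework alternates motion estimation
and motion-compensated reconstruction. Convergence is automated: stop when
the per-alternation final estimation loss increases or improves by less
than 1e-3 relative; the returned state is the alternation with minimum
loss. Each alternation re-initializes the estimation with a fresh seed
derived from the master seed (a config switch enables warm starts). The
reference motion state is whatever state the corrupted reconstruction
implicitly averages to; no re-anchoring to a named respiratory phase is
attempted.

## Operators

The projector is Joseph-style ray tracing: for each source-to-pixel ray
the trilinear volume model is sampled on the voxel planes of the ray's
dominant axis and weighted by the per-slice intersection length. The
backprojector scatters with identical weights, making it the *exact*
algebraic transpose — the property both the SIRT normalizations and the
analytic gradient require (verified to ~1e-14 against densely
materialized matrices). Geometry: flat detector, circular trajectory about
the z (superior-inferior) axis, world coordinates in mm with the isocenter
at the volume center, gantry angle 0 placing the source on +y, angles
counter-clockwise viewed from +z. Source-to-isocenter defaults to 1000 mm
(SDD 1536 mm, 512^2 detector at 0.8 mm at full scale).

Warping samples out-of-domain as 0 (air) rather than edge-clamping, and
displacement fields are stored in mm and converted to voxel units per axis
inside the kernels, which keeps anisotropic voxels correct.

A note on projector accuracy checks: comparing the projection of a
voxelized uniform ball per-ray against the chord-length formula is only
meaningful away from the rim — near tangency the chord function has
unbounded derivative and no grid-sampled representation can follow it.
Our ball check therefore band-limits the ball (1-voxel linear ramp edge),
compares against the closed-form line integral of that exact profile
(which reduces to `2*sqrt(R^2-d^2)` in the hard limit), and measures
relative L2 over all rays with chord > 2 voxels (<1%). Per-ray accuracy
is certified separately on flat-faced objects (cube, 0.1-voxel
ray-marching oracle, <0.5%).

## Synthetic data generator

The phantom is a parametric additive-ellipsoid thorax at desk scale: a
soft-tissue body (0.020 /mm), two low-attenuation lungs (net 0.004 /mm)
clipped at a sharp axial diaphragm-like plane, a homogeneous liver-like
region below it (0.025 /mm), a tumor-like sphere in one lung, and six
rib-like dense inclusions. Structure edges are smoothed over ~1 voxel so
the voxelization is band-limited for the projector; the diaphragm
interface remains sharp at the voxel scale. It deliberately reproduces
only the features the method interacts with: a high-contrast interface
where motion is strongly encoded in projections, a homogeneous region
where it is not, and bony confounders. It does not model realistic
anatomy, scatter, beam hardening, polychromatic spectra or detector lag,
so passing tests show correct mechanics of the method, not clinical image
quality.

Respiratory motion: per breathing cycle, period and amplitude are drawn
uniformly within a jitter fraction (default 10%) of their means (period
5 s; amplitude default 15 mm, within the clinically observed 5–30 mm
range), and the within-cycle profile is `sin^2`. By default each cycle is
centered on its mean ("mid-ventilation" baseline, +-A/2), so the static
ground-truth phantom sits in the state a breathing-averaged reconstruction
gravitates toward; an "exhale" baseline (0..A) is available for recovery
experiments where the reference is supplied explicitly. The spatial
envelope is 1 below the diaphragm and decays smoothly toward the lung
apex, with axis weights (0.10, 0.15, -1.00): superior-inferior dominated.
Ground truth is available both as dense per-frame fields and as an exact
rank-1 instance of the spline model (spatial coefficients sample the
envelope at the control points; temporal coefficients are the
least-squares spline fit of the profile) — the latter enables recovery
tests free of model mismatch.

Noise: counts are `Poisson(s0 exp(-y)) + Normal(0, sigma_e^2)` with
`s0 = 1e5` and `sigma_e^2 = 10`, rounded and floored at 0; a noise-free
switch replaces both draws by their means.

The acquisition protocol is 160 frames, 182 ms apart, uniformly covering
180 degrees; desk-scale variants shrink the detector grid while scaling
the pixel pitch up so the field of view and magnification are preserved.

## Metrics

SSIM uses the standard Gaussian-window formulation (sigma 1.5, population
covariances, K1/K2 = 0.01/0.03), averaged over a field-of-view mask when
given. Edge sharpness fits `offset + amplitude * Phi((x - x0)/w)` (the
error-function edge-spread of a Gaussian line-spread) by least squares and
reports the width `w`; `1/w` is the resolution proxy. Motion accuracy is
the per-axis RMSE between displacement-versus-time profiles at a chosen
voxel.

## Problem sizes used in tests and the acceptance script

Full-scale settings (256^3 grid, 512^2 detector, 200 SIRT iterations, 100
epochs, 50 alternations) are the configuration defaults. The test suite
and the acceptance script run desk-scale versions chosen as the package's
own verification sizes:

* operator/dense-matrix checks: 8^3 grid, 16^2 detector, 20 frames, where
  the system matrix can be materialized exactly;
* motion recovery: 64^3 grid (4 mm voxels), 64^2 detector, all 160
  frames, rank-1 sinusoidal z-motion of 10 mm amplitude and 5 s period,
  true phantom as reference, 12^3 spatial control points, 60 NAdam epochs,
  three seeds — recovered z-profiles are sub-voxel (RMSE well under 4 mm,
  correlation > 0.99);
* end-to-end alternation: 32^3 grid, 32^2 detector, 160 noisy frames,
  30 mm sinusoidal motion (the top of the clinically observed amplitude
  range — at this voxel size smaller motion corrupts the image less than
  the iteration-count floor of the solver, so the comparison would measure
  solver convergence instead of motion correction), 8^3 control points, 60
  epochs, 100 SIRT iterations, 2 alternations in the test suite and 3 in
  the acceptance script;
* noise moments: 10^6 air-ray samples; ESF: 201-sample synthetic edges.

## Numerical choices and degenerate inputs

* Counts are clamped at 1 before the log (detector zeros under heavy
  noise).
* SIRT normalization floors: 1e-6 of the median positive entry.
* Non-finite losses abort with the epoch/iteration index; empty ROIs,
  mismatched grids and frame counts, non-increasing timestamps and
  negative counts are rejected at the boundary.
* `MotionParameters` carries the world-space span of its spatial knot
  vector, so fields evaluate consistently on the FOV grid and on the
  extended reconstruction domain.
* Everything stochastic flows from explicit integer seeds; identical
  seeds reproduce losses and images bitwise.

## Known limitations

* The projector is single-threaded CPU (numba); full-scale clinical
  volumes are out of desk-scale runtime, which is why the defaults are
  exercised at reduced grids.
* Sliding motion violates the smoothness prior, and motion in homogeneous
  regions is weakly encoded in projections; neither is solved here (the
  regularizer simply favors smooth fields).
* The normalized push is an approximate inverse warp; its error grows
  with field gradient (quantified by `compose_check`).
* No scatter, beam hardening, detector lag, or polychromatic effects.
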