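# cbctmotion

Gate-less, model-based estimation and correction of non-rigid motion in
cone-beam CT (CBCT) reconstruction.

CBCT scans used for patient positioning in radiotherapy take tens of
seconds, so breathing and other motion blur the images. Conventional
mitigation gates projections into respiratory phases, which assumes
periodicity and fails on irregular motion. This package estimates a dense
3D motion field *per projection frame* (182 ms temporal resolution at the
clinical protocol) directly in projection space, and feeds it into a
motion-compensated iterative reconstruction — no gating, no surrogate
signal. It is aimed at researchers in tomographic image reconstruction and
image-guided radiotherapy who want a transparent, fully seeded CPU
reference implementation with a built-in dynamic digital phantom.

## The model

Counts follow mono-energetic Beer–Lambert attenuation,
`s_t = s0 · exp(−y_t)`, and the line integrals are linear in the volume,
`y_t = A_t x_t`, with `A_t` the cone-beam system matrix of frame `t`.
Frames are tied to one reference image `x0` through a displacement field
parameterized by a low-rank cubic-B-spline model

    D_t(r) = r + Σ_c σ_c(r) · τ_c(t),

where each component is a smooth spatial vector field `σ_c` (tensor-product
cubic B-splines) scaled by a smooth temporal profile `τ_c`. Motion
coefficients `c` minimize

    L(c) = Σ_t ‖ A_t x0[D_t(r|c)] − y_t ‖² + λ R,

with `R` the squared-L2 norm of the displacement gradients (λ = 1e-6), by
NAdam (γ = 0.1) with exact analytic gradients. Reconstruction is
motion-compensated SIRT,

    x ← max(0, x + C Σ_t W_t⁻¹{ A_tᵀ R_t (y_t − A_t W_t{x}) }),

where `W_t` is a trilinear pull warp and `W_t⁻¹` the normalized push
(adjoint splat). The full framework alternates motion estimation and
motion-compensated reconstruction, starting from the uncompensated
("motion-corrupted") image, until the estimation loss stops improving.

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices, and what the synthetic phantom does and does not emulate.

## Worked example

`examples/02_estimate_motion.py` simulates a breathing thorax phantom
(160 frames, 180° arc, 5 s breathing period, 10 mm amplitude) and recovers
the motion using the true phantom as reference:

```
loss: 1212.8 -> 4.629 over 60 epochs
per-axis RMSE vs ground truth at the tracked voxel: x 0.12 mm, y 0.03 mm, z 0.04 mm (voxel = 8 mm)
```

The z-displacement trace of a voxel on the lung–liver-like interface is
recovered to a small fraction of a voxel — the 182 ms-resolved breathing
curve is readable from single-angle projections because the temporal
spline couples neighbouring frames. `examples/03_full_reconstruction.py`
runs the full alternation on noisy data and prints

```
alternation losses: [324.05841129 139.02088032  79.63107113]
converged at alternation index 2
SSIM vs static truth: corrupted 0.9721 -> corrected 0.9828
```

i.e. each alternation lowers the estimation loss and the motion-corrected
image is structurally closer to the static ground truth than the
uncompensated one.

A thin CLI mirrors the library for shell use:

```bash
cbctmotion simulate --out sim --size 32 --frames 160 --seed 0
cbctmotion run --projections sim/projections.h5 --out run --size 32 --voxel-mm 8
cbctmotion evaluate --result run --truth sim/phantom.mha --out metrics
```

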