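"""Low-rank B-spline motion model: bases, field evaluation, Jacobians."""

import numpy as np
import pytest

import cbctmotion as cm
from cbctmotion.geometry import ValidationError
from cbctmotion.motion import (
    SplineConfig,
    bspline_design_matrix,
    clamped_knots,
    spatial_basis,
    temporal_basis,
)


def cox_de_boor(x, t, i, k):
    """Textbook Cox-de Boor recursion for basis element i of degree k."""
    if k == 0:
        return 1.0 if t[i] <= x < t[i + 1] else 0.0
    out = 0.0
    if t[i + k] > t[i]:
        out += (x - t[i]) / (t[i + k] - t[i]) * cox_de_boor(x, t, i, k - 1)
    if t[i + k + 1] > t[i + 1]:
        out += (t[i + k + 1] - x) / (t[i + k + 1] - t[i + 1]) * cox_de_boor(x, t, i + 1, k - 1)
    return out


class TestBasis:
    def test_partition_of_unity(self):
        x = np.linspace(-3.0, 7.0, 311)
        B = bspline_design_matrix(x, -3.0, 7.0, 9)
        assert np.abs(B.sum(axis=1) - 1.0).max() < 1e-10

    def test_matches_cox_de_boor(self, rng):
        a, b, n = -2.0, 5.0, 8
        t = clamped_knots(a, b, n)
        x = rng.uniform(a, b, 100)
        B = bspline_design_matrix(x, a, b, n)
        oracle = np.array([[cox_de_boor(xx, t, i, 3) for i in range(n)] for xx in x])
        assert np.abs(B - oracle).max() < 1e-10

    def test_too_few_control_points(self):
        with pytest.raises(ValidationError):
            bspline_design_matrix(np.array([0.0]), 0.0, 1.0, 3)
        with pytest.raises(ValidationError):
            SplineConfig((3, 8, 8), 2.0)

    def test_constant_coefficients_give_constant_field(self, medium_grid):
        """All-equal coefficients reproduce the constant (PoU corollary)."""
        Bx, By, Bz = spatial_basis(SplineConfig((5, 6, 7), 2.0), medium_grid)
        c = np.full((5, 6, 7), 3.25)
        field = np.einsum("xi,yj,zk,ijk->xyz", Bx, By, Bz, c)
        assert np.abs(field - 3.25).max() < 1e-9


class TestTemporalBasis:
    def test_rows_sum_to_one(self):
        cfg = SplineConfig((4, 4, 4), 2.0)
        ts = 0.182 * np.arange(160)
        Bt = temporal_basis(cfg, ts)
        assert np.abs(Bt.sum(axis=1) - 1.0).max() < 1e-10

    def test_29s_scan_at_2_per_s_has_58_segments(self):
        """Protocol duration x rate 2.0/s -> 58 interior knots (61 coeffs)."""
        cfg = SplineConfig((4, 4, 4), 2.0)
        ts = 0.182 * np.arange(160)
        assert cfg.n_temporal_segments(ts[-1] - ts[0]) == 58
        assert temporal_basis(cfg, ts).shape == (160, 61)

    def test_constant_coefficients_constant_profile(self):
        cfg = SplineConfig((4, 4, 4), 1.0)
        ts = np.linspace(0, 10, 37)
        Bt = temporal_basis(cfg, ts)
        profile = Bt @ np.full(Bt.shape[1], 4.5)
        assert np.allclose(profile, 4.5, atol=1e-10)

    def test_empty_timestamps_rejected(self):
        with pytest.raises(ValidationError):
            temporal_basis(SplineConfig((4, 4, 4), 2.0), np.array([]))


class TestMotionField:
    def test_zero_coefficients_identity_motion(self, medium_grid):
        params = cm.MotionParameters.zeros(SplineConfig((4, 4, 4), 2.0), (0.0, 5.0))
        fld = cm.evaluate_motion_field(params, medium_grid, 2.0)
        assert np.all(fld.displacement == 0.0)

    def test_uniform_translation_from_partition_of_unity(self, medium_grid):
        """Spatial z-coeffs 3 mm, temporal value 0.5 -> uniform 1.5 mm shift."""
        cfg = SplineConfig((5, 5, 5), 2.0)
        params = cm.MotionParameters.zeros(cfg, (0.0, 5.0))
        params.spatial[0, 2] = 3.0
        params.temporal[0] = 0.5  # constant profile 0.5 by PoU
        fld = cm.evaluate_motion_field(params, medium_grid, 1.7)
        assert np.allclose(fld.displacement[..., 2], 1.5, atol=1e-10)
        assert np.allclose(fld.displacement[..., :2], 0.0, atol=1e-12)

    def test_matches_nested_loop_oracle(self, medium_grid, rng):
        cfg = SplineConfig((5, 4, 6), 2.0)
        params = cm.MotionParameters.zeros(cfg, (0.0, 8.0), n_components=2)
        params.spatial[:] = rng.normal(size=params.spatial.shape)
        params.temporal[:] = rng.normal(size=params.temporal.shape)
        t = 3.3
        fld = cm.evaluate_motion_field(params, medium_grid, t)
        Bx, By, Bz = spatial_basis(cfg, medium_grid)
        Bt = temporal_basis(cfg, np.array([t]), (0.0, 8.0))
        for _ in range(50):
            i, j, k = (int(v) for v in rng.integers(0, medium_grid.shape[0], 3))
            for p in range(3):
                val = 0.0
                for c in range(2):
                    tau = float(Bt[0] @ params.temporal[c])
                    s = 0.0
                    for a in range(5):
                        for b in range(4):
                            for d in range(6):
                                s += Bx[i, a] * By[j, b] * Bz[k, d] * params.spatial[c, p, a, b, d]
                    val += s * tau
                assert abs(val - fld.displacement[i, j, k, p]) < 1e-8

    def test_zero_components_rejected(self):
        with pytest.raises(ValidationError):
            cm.MotionParameters.zeros(SplineConfig((4, 4, 4), 2.0), (0.0, 5.0), n_components=0)

    def test_parameter_count(self):
        cfg = SplineConfig((5, 6, 7), 2.0)
        params = cm.MotionParameters.zeros(cfg, (0.0, 10.0), n_components=2)
        n_temporal = cfg.n_temporal_ctrl(10.0)
        assert params.n_parameters == 2 * (3 * 5 * 6 * 7 + n_temporal)

    def test_low_rank_separability(self, medium_grid, rng):
        """For fixed spatial coeffs the voxel displacement is linear in tau."""
        cfg = SplineConfig((4, 4, 4), 1.0)
        params = cm.MotionParameters.zeros(cfg, (0.0, 6.0))
        params.spatial[:] = rng.normal(size=params.spatial.shape)
        params.temporal[:] = rng.normal(size=params.temporal.shape)
        taus = params.temporal_profiles(np.array([1.0, 2.5, 4.0]))[0]
        fields = [cm.evaluate_motion_field(params, medium_grid, t).displacement
                  for t in (1.0, 2.5, 4.0)]
        # displacement(t) = sigma * tau(t): ratios of fields equal ratios of tau
        sigma = fields[0] / taus[0]
        for tau, fld in zip(taus[1:], fields[1:]):
            assert np.allclose(fld, sigma * tau, rtol=1e-9, atol=1e-12)


class TestJacobian:
    def test_zero_and_translation_give_zero_tensor(self, medium_grid):
        cfg = SplineConfig((5, 5, 5), 2.0)
        params = cm.MotionParameters.zeros(cfg, (0.0, 5.0))
        assert np.all(cm.motion_jacobian(params, medium_grid, 2.0) == 0.0)
        params.spatial[0, 0] = 4.0
        params.spatial[0, 2] = -2.0
        params.temporal[0] = 1.0
        jac = cm.motion_jacobian(params, medium_grid, 2.0)
        assert np.abs(jac).max() < 1e-10

    def test_matches_finite_differences(self, medium_grid, rng):
        from cbctmotion.motion import _axis_domain

        cfg = SplineConfig((5, 4, 6), 2.0)
        params = cm.MotionParameters.zeros(cfg, (0.0, 8.0), n_components=2)
        params.spatial[:] = rng.normal(size=params.spatial.shape)
        params.temporal[:] = rng.normal(size=params.temporal.shape)
        jac = cm.motion_jacobian(params, medium_grid, 3.0)
        dom = tuple(_axis_domain(medium_grid, a) for a in range(3))
        eps = 1e-4
        scale = np.abs(jac).max()
        for d in range(3):
            o1 = list(medium_grid.origin_mm)
            o2 = list(medium_grid.origin_mm)
            o1[d] += eps
            o2[d] -= eps
            g1 = cm.VolumeGrid(medium_grid.shape, medium_grid.voxel_size_mm, tuple(o1))
            g2 = cm.VolumeGrid(medium_grid.shape, medium_grid.voxel_size_mm, tuple(o2))
            f1 = cm.evaluate_motion_field(params, g1, 3.0, spatial_domain=dom)
            f2 = cm.evaluate_motion_field(params, g2, 3.0, spatial_domain=dom)
            fd = (f1.displacement - f2.displacement) / (2 * eps)
            interior = (slice(1, -1),) * 3
            err = np.abs(fd[interior] - jac[(*interior, slice(None), d)]).max()
            assert err / scale < 1e-3

    def test_smoothness_second_differences_bounded(self, medium_grid, rng):
        """Discrete curvature never exceeds the analytic 2nd-derivative bound.

        The field is C^2 for cubic splines, and f_xx is piecewise linear in
        x, so its supremum is attained at knot/grid breakpoints; a central
        second difference is a stencil average of f_xx and must stay below
        that supremum.
        """
        from cbctmotion.motion import _axis_domain, clamped_knots

        cfg = SplineConfig((5, 5, 5), 2.0)
        params = cm.MotionParameters.zeros(cfg, (0.0, 5.0))
        params.spatial[:] = rng.normal(size=params.spatial.shape)
        params.temporal[0] = 1.0
        disp = cm.evaluate_motion_field(params, medium_grid, 2.5).displacement[..., 0]
        h = medium_grid.voxel_size_mm[0]
        second = np.abs(np.diff(disp, 2, axis=0)) / h**2

        a, b = _axis_domain(medium_grid, 0)
        xs = np.unique(np.concatenate([medium_grid.axis_coordinates(0), clamped_knots(a, b, 5)]))
        Bxx = bspline_design_matrix(xs, a, b, 5, deriv=2)
        _, By, Bz = spatial_basis(cfg, medium_grid)
        fxx = np.einsum("xi,yj,zk,ijk->xyz", Bxx, By, Bz, params.spatial[0, 0])
        assert second.max() <= np.abs(fxx).max() * (1 + 1e-9) + 1e-12
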