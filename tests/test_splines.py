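"""Spline construction, evaluation and the emitter PSF model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.interpolate import CubicSpline

from splinepsf.splines import (CubicSpline3D, EmitterParams, OutOfSupportError,
                               SplinePSF, build_spline_1d, build_spline_3d,
                               count_eval_operations, eval_psf,
                               eval_psf_gradient, gaussian_eval_operations,
                               spline_eval_operations, upsample_stack)
from splinepsf.stack import PSFStack, resample_z


def dense_natural_solve(values):
    """Independent oracle: assemble and solve the full natural-spline system.

    Unknowns are the 4 coefficients (a, b, c, d) of every interval;
    equations are interpolation at both interval ends, C1/C2 continuity at
    interior knots, and zero curvature at the two boundary knots.
    """
    values = np.asarray(values, float)
    n = len(values) - 1
    rows, rhs = [], []

    def eq(coeffs_per_interval, value):
        row = np.zeros(4 * n)
        for (i, m), c in coeffs_per_interval.items():
            row[4 * i + m] = c
        rows.append(row)
        rhs.append(value)

    for i in range(n):
        eq({(i, 3): 1.0}, values[i])                      # f_i(0) = y_i
        eq({(i, 0): 1, (i, 1): 1, (i, 2): 1, (i, 3): 1}, values[i + 1])
    for i in range(n - 1):                                # C1, C2
        eq({(i, 0): 3, (i, 1): 2, (i, 2): 1, (i + 1, 2): -1}, 0.0)
        eq({(i, 0): 6, (i, 1): 2, (i + 1, 1): -2}, 0.0)
    eq({(0, 1): 1.0}, 0.0)                                # natural ends
    eq({(n - 1, 0): 3, (n - 1, 1): 1}, 0.0)
    sol, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    return sol.reshape(n, 4)


class TestSpline1D:
    def test_constant_input_gives_constant_polynomials(self):
        sp = build_spline_1d([5.0] * 6)
        assert np.allclose(sp.coefficients[:, :3], 0.0, atol=1e-12)
        assert np.allclose(sp.coefficients[:, 3], 5.0)

    def test_coefficients_match_dense_linear_system_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=10)
        sp = build_spline_1d(values)
        assert np.allclose(sp.coefficients, dense_natural_solve(values),
                           atol=1e-9)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=20))
    def test_interpolation_and_continuity(self, values):
        sp = build_spline_1d(values)
        knots = np.arange(len(values), dtype=float)
        scale = 1.0 + np.max(np.abs(values))
        assert np.allclose(sp(knots), values, atol=1e-9 * scale)
        interior = knots[1:-1]
        eps = 1e-7
        # two-sided evaluation differs by O(eps * f'), so scale the bound
        assert np.allclose(sp(interior - eps), sp(interior + eps),
                           atol=1e-5 * scale)
        assert np.allclose(sp.derivative(interior - eps),
                           sp.derivative(interior + eps), atol=1e-4 * scale)

    def test_natural_boundary_condition(self):
        sp = build_spline_1d(np.sin(np.linspace(0, 3, 9)))
        assert sp.second_derivative(0.0) == pytest.approx(0.0, abs=1e-12)
        assert sp.second_derivative(8.0) == pytest.approx(0.0, abs=1e-12)

    def test_cubic_samples_interpolated_exactly_at_knots(self):
        x = np.arange(9, dtype=float)
        sp = build_spline_1d(x**3)
        assert np.allclose(sp(x), x**3, atol=1e-9)
        # between knots the natural end condition perturbs the boundary
        # intervals; deep interior intervals approach the true cubic
        mid = 4.5
        assert sp(mid) == pytest.approx(mid**3, rel=1e-3)

    @pytest.mark.parametrize("bad", [[1.0], [], [1.0, np.nan], [np.inf, 0.0]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            build_spline_1d(bad)


class TestUpsampleStack:
    def _stack(self, data):
        data = np.asarray(data, float)
        return PSFStack(data, np.arange(data.shape[0]) * 50.0, 160.0)

    def test_factor_one_is_identity(self):
        st_ = self._stack(np.random.default_rng(0).random((4, 4, 4)))
        out = upsample_stack(st_, 1)
        assert np.array_equal(out.data, st_.data)

    def test_constant_stack_stays_constant(self):
        out = upsample_stack(self._stack(np.full((3, 3, 3), 2.5)), 2)
        assert out.data.shape == (5, 5, 5)
        assert np.allclose(out.data, 2.5, atol=1e-12)

    def test_linear_ramp_midpoints_are_neighbor_means(self):
        ramp = np.broadcast_to(np.arange(5.0), (5, 5, 5)).copy()
        out = upsample_stack(self._stack(ramp), 2)
        mids = out.data[0, 0, 1::2]
        assert np.allclose(mids, 0.5 * (ramp[0, 0, :-1] + ramp[0, 0, 1:]),
                           atol=1e-9)

    def test_original_samples_preserved_and_pixel_size_scaled(self):
        st_ = self._stack(np.random.default_rng(1).random((4, 4, 4)))
        out = upsample_stack(st_, 2)
        assert np.allclose(out.data[::2, ::2, ::2], st_.data, atol=1e-12)
        assert out.pixel_size == pytest.approx(80.0)

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            upsample_stack(self._stack(np.ones((3, 3, 3))), 0)


@pytest.fixture(scope="module")
def random_stack():
    rng = np.random.default_rng(7)
    return PSFStack(rng.random((6, 6, 6)), np.arange(6.0) * 50.0, 80.0)


class TestSpline3D:

    def test_knot_exactness(self, random_stack):
        sp = build_spline_3d(random_stack)
        k = np.arange(6.0)
        vals = sp.evaluate(k[:, None, None], k[None, :, None], k[None, None, :])
        assert np.allclose(vals, random_stack.data, rtol=1e-9, atol=1e-12)

    def test_64_coefficients_per_interval(self, random_stack):
        sp = build_spline_3d(random_stack)
        assert sp.coefficients.shape == (5, 5, 5, 4, 4, 4)

    def test_value_and_gradient_continuity_at_interval_boundaries(
            self, random_stack):
        sp = build_spline_3d(random_stack)
        eps = 1e-7
        pts = np.array([1.0, 2.0, 3.0, 4.0])
        for axis in range(3):
            coords_lo = [np.full_like(pts, 2.3)] * 3
            coords_hi = [np.full_like(pts, 2.3)] * 3
            coords_lo[axis] = pts - eps
            coords_hi[axis] = pts + eps
            lo = sp.evaluate_with_gradient(*coords_lo)
            hi = sp.evaluate_with_gradient(*coords_hi)
            assert np.allclose(lo[0], hi[0], rtol=1e-6, atol=1e-9)
            for g_lo, g_hi in zip(lo[1:], hi[1:]):
                assert np.allclose(g_lo, g_hi, rtol=1e-4, atol=1e-5)

    def test_matches_sequential_scipy_natural_spline_oracle(self, random_stack):
        sp = build_spline_3d(random_stack)
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 5, size=(40, 3))
        mine = sp.evaluate(pts[:, 0], pts[:, 1], pts[:, 2])
        idx = np.arange(6)
        oracle = []
        for tz, ty, tx in pts:
            a = CubicSpline(idx, random_stack.data, axis=0,
                            bc_type="natural")(tz)
            b = CubicSpline(idx, a, axis=0, bc_type="natural")(ty)
            oracle.append(CubicSpline(idx, b, axis=0, bc_type="natural")(tx))
        assert np.allclose(mine, np.asarray(oracle), rtol=1e-9, atol=1e-12)

    def test_separable_cubic_reproduced_on_interior_intervals(self):
        # the natural end condition perturbs boundary intervals; deep
        # interior intervals carry only the geometrically-decayed remnant
        n = 13
        g = lambda t: 0.05 * t**3 - 0.4 * t**2 + t + 3.0
        idx = np.arange(n, dtype=float)
        data = (g(idx)[:, None, None] * g(idx)[None, :, None]
                * g(idx)[None, None, :])
        sp = build_spline_3d(PSFStack(data, idx * 50.0, 80.0))
        t = np.linspace(5.0, 7.0, 9)
        vals = sp.evaluate(t[:, None, None], t[None, :, None], t[None, None, :])
        exact = g(t)[:, None, None] * g(t)[None, :, None] * g(t)[None, None, :]
        assert np.allclose(vals, exact, rtol=1e-4)

    @pytest.mark.parametrize("shape", [(4, 5, 5), (1, 1, 1)])
    def test_invalid_stacks_rejected(self, shape):
        data = np.ones(shape)
        with pytest.raises(ValueError):
            build_spline_3d(PSFStack(data, np.arange(shape[0]) * 50.0, 80.0))

    def test_serialization_round_trip(self, random_stack, tmp_path):
        sp = build_spline_3d(random_stack)
        path = tmp_path / "spline.h5"
        sp.save(path)
        back = CubicSpline3D.load(path)
        assert np.array_equal(back.coefficients, sp.coefficients)
        assert back.du_nm == sp.du_nm and back.z_min_nm == sp.z_min_nm


class TestEmitterModel:
    def test_h_zero_gives_flat_baseline(self, spline_astig):
        img = eval_psf(spline_astig,
                       EmitterParams(x=5.5, y=5.5, z=0.0, h=0.0, b=3.0),
                       (12, 12))
        assert np.allclose(img, 3.0, atol=1e-12)

    def test_center_pixel_equals_knot_value_at_focus(self, spline_astig,
                                                     ref_astig):
        # emitter centered on the ROI: the center pixel samples the spline
        # at a lateral knot
        size = 13
        c = (size - 1) / 2.0
        img = eval_psf(spline_astig,
                       EmitterParams(x=c, y=c, z=0.0, h=1.0, b=0.0),
                       (size, size))
        sp = spline_astig.spline
        center = sp.n_intervals[2] / 2.0
        z0 = (0.0 - sp.z_min_nm) / sp.du_nm
        assert img[size // 2, size // 2] == pytest.approx(
            float(sp.evaluate(z0, center, center)), rel=1e-9)

    def test_subpixel_evaluation_matches_scipy_tensor_oracle(self, ref_astig):
        model = SplinePSF.from_psf_stack(
            PSFStack(ref_astig.data[::1], ref_astig.z_positions,
                     ref_astig.pixel_size), normalize=False)
        params = EmitterParams(x=5.37, y=5.81, z=137.0, h=1.0, b=0.0)
        img = eval_psf(model, params, (12, 12))
        sp = model.spline
        # the model resamples z to the lateral knot count before building
        nz = sp.n_intervals[0] + 1
        data = ref_astig.data
        if data.shape[0] != nz:
            z_pos = np.linspace(0, data.shape[0] - 1.0, nz)
            data = CubicSpline(np.arange(data.shape[0]), data, axis=0,
                               bc_type="natural")(z_pos)
        idx_z = np.arange(nz, dtype=float)
        idx_lat = np.arange(data.shape[-1], dtype=float)
        tz = (params.z - sp.z_min_nm) / sp.du_nm
        plane = CubicSpline(idx_z, data, axis=0, bc_type="natural")(tz)
        kpp = model.pixel_size / sp.dt_nm
        ty = kpp * (np.arange(12) - params.y) + sp.n_intervals[1] / 2.0
        tx = kpp * (np.arange(12) - params.x) + sp.n_intervals[2] / 2.0
        rows = CubicSpline(idx_lat, plane, axis=0, bc_type="natural")(ty)
        oracle = CubicSpline(idx_lat, rows, axis=1, bc_type="natural")(tx)
        assert np.allclose(img, oracle, rtol=1e-6, atol=1e-12)

    def test_out_of_support_raises(self, spline_astig):
        with pytest.raises(OutOfSupportError):
            eval_psf(spline_astig,
                     EmitterParams(x=11.0, y=5.5, z=0.0, h=1.0, b=0.0),
                     (12, 12))
        with pytest.raises(OutOfSupportError):
            eval_psf(spline_astig,
                     EmitterParams(x=5.5, y=5.5, z=5000.0, h=1.0, b=0.0),
                     (12, 12))

    def test_baseline_partial_is_identically_one(self, spline_astig):
        jac = eval_psf_gradient(
            spline_astig, EmitterParams(x=5.5, y=5.5, z=50.0, h=900.0, b=7.0),
            (12, 12))
        assert np.array_equal(jac[4], np.ones((12, 12)))

    def test_height_partial_consistent_with_model(self, spline_astig):
        params = EmitterParams(x=5.5, y=5.5, z=-120.0, h=800.0, b=5.0)
        img = eval_psf(spline_astig, params, (12, 12))
        jac = eval_psf_gradient(spline_astig, params, (12, 12))
        assert np.allclose(jac[0], (img - params.b) / params.h, rtol=1e-9)

    def test_x_partial_antisymmetric_for_centered_symmetric_psf(
            self, spline_symmetric):
        size = 13
        c = (size - 1) / 2.0
        jac = eval_psf_gradient(
            spline_symmetric, EmitterParams(x=c, y=c, z=0.0, h=1.0, b=0.0),
            (size, size))
        assert np.allclose(jac[1], -jac[1][:, ::-1], atol=1e-9)

    def test_gradient_matches_finite_differences(self, spline_astig):
        rng = np.random.default_rng(5)
        shape = (12, 12)
        steps = np.array([1.0, 1e-4, 1e-4, 1e-2, 1.0])  # h, x, y, z, b
        for _ in range(100):
            p = np.array([rng.uniform(500, 5000),
                          rng.uniform(4.6, 6.4), rng.uniform(4.6, 6.4),
                          rng.uniform(-450, 450), rng.uniform(2, 50)])
            params = EmitterParams(x=p[1], y=p[2], z=p[3], h=p[0], b=p[4])
            jac = eval_psf_gradient(spline_astig, params, shape)
            for k in range(5):
                dp = np.zeros(5)
                dp[k] = steps[k]
                hi = eval_psf(spline_astig, EmitterParams(
                    x=p[1] + dp[1], y=p[2] + dp[2], z=p[3] + dp[3],
                    h=p[0] + dp[0], b=p[4] + dp[4]), shape)
                lo = eval_psf(spline_astig, EmitterParams(
                    x=p[1] - dp[1], y=p[2] - dp[2], z=p[3] - dp[3],
                    h=p[0] - dp[0], b=p[4] - dp[4]), shape)
                fd = (hi - lo) / (2 * steps[k])
                scale = np.max(np.abs(fd)) + 1e-9
                assert np.allclose(jac[k], fd, atol=1e-4 * scale)


class TestOperationCount:
    def test_tricubic_costs_128_operations(self):
        assert spline_eval_operations(order=3, ndim=3) == 128
        assert count_eval_operations("spline") == 128

    def test_elliptical_gaussian_costs_10_operations(self):
        assert gaussian_eval_operations() == 10
        assert count_eval_operations("gaussian") == 10

    def test_1d_cubic_costs_8_operations(self):
        assert spline_eval_operations(order=3, ndim=1) == 8


class TestResampleZ:
    def test_preserves_endpoints_and_count(self):
        rng = np.random.default_rng(2)
        st_ = PSFStack(rng.random((9, 5, 5)), np.linspace(-200, 200, 9), 80.0)
        out = resample_z(st_, 5)
        assert out.data.shape == (5, 5, 5)
        assert out.z_positions[0] == -200 and out.z_positions[-1] == 200
        assert np.allclose(out.data[0], st_.data[0], atol=1e-12)
        assert np.allclose(out.data[-1], st_.data[-1], atol=1e-12)
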