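"""Warp construction: B-spline basis, monotone builds, inversion, penalty."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abrwarp import (
    SplineBasis,
    TimeWindow,
    WarpFunction,
    bspline_basis,
    build_warp,
    eval_logderiv,
    invert_warp,
    roughness_penalty,
    warp_response,
)


class TestTimeWindow:
    def test_sample_count_matches_rate(self):
        # 12 ms at 16.384 kHz -> ceil(196.608) = 197 samples
        assert TimeWindow.from_fs(0, 12, 16384).n_samples == 197

    def test_normalized_coordinates_round_trip(self, window):
        t_ms = np.array([0.0, 3.3, 12.0])
        assert np.allclose(window.to_ms(window.to_norm(t_ms)), t_ms)

    def test_rejects_empty_window(self):
        with pytest.raises(ValueError):
            TimeWindow(5.0, 5.0, 10)


class TestBsplineBasis:
    def test_knot_spacing_is_one_ms_for_default_knots(self):
        # K=13 knots on a 0-12 ms window space the knots exactly 1 ms apart
        basis = SplineBasis(13)
        window = TimeWindow.from_fs(0, 12, 16384)
        assert window.duration_ms * basis.dt == pytest.approx(1.0)

    @pytest.mark.parametrize("k", range(2, 13))
    def test_hat_apex_and_support_edges(self, k):
        basis = SplineBasis(13)
        t_k, t_next, t_prev = basis.knots[k - 1], basis.knots[k], basis.knots[k - 2]
        assert bspline_basis(t_k, k, basis) == pytest.approx(1.0)  # apex
        assert bspline_basis(t_next, k, basis) == pytest.approx(0.0)  # support edge
        assert bspline_basis(t_prev, k, basis) == pytest.approx(0.0)
        mid = (t_k + t_next) / 2.0
        assert bspline_basis(mid, k, basis) == pytest.approx(0.5)

    def test_domain_errors(self):
        basis = SplineBasis(5)
        with pytest.raises(ValueError):
            bspline_basis(1.5, 2, basis)
        with pytest.raises(ValueError):
            bspline_basis(0.5, 0, basis)
        with pytest.raises(ValueError):
            bspline_basis(0.5, 6, basis)

    def test_logderiv_interpolates_coefficients(self):
        basis = SplineBasis(4)
        coeffs = np.array([0.0, 1.0, 0.0, 0.0])
        # w(t_k) = c_k exactly
        assert eval_logderiv(coeffs, basis.knots[1], basis) == pytest.approx(1.0)
        # midway between knots 1 and 2 the hat contributes half its apex
        mid = (basis.knots[0] + basis.knots[1]) / 2
        assert eval_logderiv(coeffs, mid, basis) == pytest.approx(0.5)
        assert np.allclose(eval_logderiv(np.zeros(4), np.linspace(0, 1, 11), basis), 0.0)

    def test_logderiv_shape_error(self):
        with pytest.raises(ValueError):
            eval_logderiv(np.zeros(3), 0.5, SplineBasis(4))


class TestBuildWarp:
    def test_zero_coefficients_give_identity(self, window):
        h = build_warp(np.zeros(13), window)
        assert np.allclose(h.values, h.grid, atol=1e-12)

    @pytest.mark.parametrize("c0", [-2.0, 0.7, 5.0])
    def test_constant_coefficients_give_identity(self, window, c0):
        # the normalization constant absorbs any constant log-derivative
        h = build_warp(np.full(13, c0), window)
        assert np.allclose(h.values, h.grid, atol=1e-9)

    def test_matches_fine_quadrature_oracle(self, window):
        coeffs = 0.5 * np.arange(13) / 12.0
        h = build_warp(coeffs, window, n_grid=1201)
        oracle = build_warp(coeffs, window, n_grid=10**6)
        assert abs(h(0.5) - oracle(0.5)) < 1e-4

    def test_endpoints_pinned(self, window):
        h = build_warp(np.linspace(-1, 1, 13), window)
        assert h.values[0] == 0.0
        assert h.values[-1] == 1.0

    def test_monotone_for_any_finite_coefficients(self, window, rng):
        # monotonicity is structural, not an optimization outcome
        for _ in range(1000):
            coeffs = rng.uniform(-5, 5, size=13)
            h = build_warp(coeffs, window)
            assert np.all(np.diff(h.values) > 0)

    def test_rejects_non_finite_coefficients(self, window):
        with pytest.raises(ValueError):
            build_warp([0.0] * 12 + [np.nan], window)

    def test_json_round_trip(self, window):
        h = build_warp(np.linspace(-0.5, 0.5, 13), window)
        h2 = WarpFunction.from_json(h.to_json())
        assert np.allclose(h2.coeffs, h.coeffs)
        assert np.allclose(h2.values, h.values)
        assert json.loads(h.to_json())["K"] == 13


class TestWarpResponse:
    def test_identity_warp_is_identity(self, window, rng):
        x = rng.standard_normal(window.n_samples)
        h = build_warp(np.zeros(13), window)
        assert np.allclose(warp_response(x, h), x)

    def test_constant_input_unchanged_by_any_warp(self, window, rng):
        x = np.full(window.n_samples, 3.7)
        h = build_warp(rng.uniform(-1, 1, 13), window)
        assert np.allclose(warp_response(x, h), 3.7)

    def test_pulse_apex_moves_to_preimage(self, window):
        # warp with h(0.4) = 0.5 pulls a pulse centred at 0.5 to t = 0.4
        from scipy.optimize import brentq

        grid = window.grid
        x = np.maximum(0.0, 1.0 - np.abs(grid - 0.5) / 0.1)

        def h_at_04(c1):
            coeffs = np.zeros(13)
            coeffs[:6] = c1
            return build_warp(coeffs, window)(0.4) - 0.5

        c1 = brentq(h_at_04, 0.0, 3.0)
        coeffs = np.zeros(13)
        coeffs[:6] = c1
        h = build_warp(coeffs, window)
        apex = grid[np.argmax(warp_response(x, h))]
        assert abs(apex - 0.4) <= 1.0 / (window.n_samples - 1)

    def test_grid_mismatch_raises(self, window):
        h = build_warp(np.zeros(13), window)
        with pytest.raises(ValueError):
            warp_response(np.zeros(window.n_samples + 1), h)


class TestInvertWarp:
    def test_identity_inverts_to_identity(self, window):
        h = build_warp(np.zeros(13), window)
        hi = invert_warp(h)
        assert np.allclose(hi.values, hi.grid, atol=1e-12)

    def test_single_point_inversion(self, window):
        from scipy.optimize import brentq

        def h_at(c1):
            coeffs = np.zeros(13)
            coeffs[:5] = c1
            return build_warp(coeffs, window, 2001)(0.25) - 0.5

        c1 = brentq(h_at, 0.0, 5.0)
        coeffs = np.zeros(13)
        coeffs[:5] = c1
        h = build_warp(coeffs, window, 2001)
        assert abs(invert_warp(h)(0.5) - 0.25) < 2.0 / 2000

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_round_trip_bounded_by_grid_resolution(self, seed):
        window = TimeWindow.from_fs(0, 12, 16384)
        rng = np.random.default_rng(seed)
        h = build_warp(rng.uniform(-1.5, 1.5, 13), window)
        hi = invert_warp(h)
        round_trip = hi(h.values)
        assert np.max(np.abs(round_trip - h.grid)) < 2.0 / (window.n_samples - 1)


class TestRoughnessPenalty:
    def test_constant_coefficients_cost_nothing(self):
        assert roughness_penalty(np.full(7, 2.5)) == 0.0

    def test_two_knot_closed_form(self):
        # K=2: slope 1 over unit interval -> integral of 1
        assert roughness_penalty(np.array([0.0, 1.0])) == pytest.approx(1.0)

    def test_matches_numeric_quadrature(self, rng):
        basis = SplineBasis(13)
        for _ in range(5):
            coeffs = rng.uniform(-2, 2, 13)
            grid = np.linspace(0, 1, 10**5)
            w = np.interp(grid, basis.knots, coeffs)
            numeric = np.sum(np.diff(w) ** 2 / np.diff(grid))
            closed = roughness_penalty(coeffs, basis)
            assert closed == pytest.approx(numeric, rel=1e-4)
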