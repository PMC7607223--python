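"""Warp fitting and the average-target / pairwise registration procedures."""

import itertools

import numpy as np
import pytest

from abrwarp import (
    LossConfig,
    OptimOptions,
    ResponseSet,
    fit_warp,
    register_at,
    register_pw,
    simulate_dataset,
    warp_accuracy,
    warp_replicates,
)
from abrwarp.registration import register
from abrwarp.validation import response_deviation
from abrwarp.warping import TimeWindow, build_warp, invert_warp, warp_response


@pytest.fixture(scope="module")
def small_window():
    return TimeWindow.from_fs(0.0, 12.0, 8192.0)  # 99 samples: keeps fits cheap


class TestFitWarp:
    def test_identical_curves_fit_to_identity(self, window, template):
        res = fit_warp(template.samples, template.samples, LossConfig("psdd", 0.0),
                       window=window)
        assert np.max(np.abs(res.warp.values - res.warp.grid)) < 0.01
        assert res.final_loss <= res.identity_loss

    def test_recovers_known_warp_noiselessly(self, window, template, rng):
        # x = S(h0^{-1}(t)): fitting x to S must recover h0
        h0 = build_warp(rng.uniform(-0.4, 0.4, 13), window)
        x = warp_response(template.samples, invert_warp(h0))
        res = fit_warp(x, template.samples, LossConfig("psdd", 0.0), window=window)
        rho, _ = warp_accuracy(h0, res.warp)
        assert rho > 0.95

    def test_beats_brute_force_grid_search(self, small_window):
        # K=3 leaves 2 effective dims (constant vectors are gauge); an
        # exhaustive scan over the coefficient box bounds the attainable loss
        grid_t = small_window.grid
        y = np.sin(2 * np.pi * grid_t) + 0.5 * np.sin(4 * np.pi * grid_t)
        h_true = build_warp(np.array([0.3, -0.2, 0.1]), small_window)
        x = warp_response(y, invert_warp(h_true))
        cfg = LossConfig("psd", 0.0)
        opts = OptimOptions(K=3)
        res = fit_warp(x, y, cfg, options=opts, window=small_window)

        from abrwarp.criteria import loss
        from abrwarp.warping import SplineBasis

        basis = SplineBasis(3)
        best = np.inf
        for c2, c3 in itertools.product(np.arange(-1, 1.001, 0.05), repeat=2):
            coeffs = np.array([0.0, c2, c3])
            h = build_warp(coeffs, small_window)
            best = min(best, loss(warp_response(x, h), y, coeffs, cfg, basis))
        assert res.final_loss <= best + 1e-3

    def test_degenerate_correlation_falls_back_to_identity(self, window):
        flat = np.zeros(window.n_samples)
        res = fit_warp(flat, flat, LossConfig("pmc", 0.0), window=window)
        assert not res.converged
        assert np.allclose(res.warp.values, res.warp.grid)


def _identical_subject_set(window, template, n=4):
    data = np.column_stack([template.samples] * n)
    return ResponseSet(
        window=window, subjects=list(range(n)), data={"bb": data},
        target_condition="bb",
    )


class TestRegisterAt:
    def test_identical_subjects_yield_identity_warps(self, window, template):
        rset = _identical_subject_set(window, template)
        res = register_at(rset, LossConfig("psdd", 0.0))
        for w in res.warps["bb"]:
            assert np.max(np.abs(w.values - w.grid)) < 0.01
        assert np.allclose(res.structural_avg["bb"], template.samples, atol=1e-3)

    def test_recovers_warps_and_tightens_deviation(self, noiseless_sim):
        rset = noiseless_sim.as_response_set(with_replicates=False)
        res = register_at(rset, LossConfig("psdd", 0.0))
        accs = [
            warp_accuracy(noiseless_sim.true_warps[i], res.warps[0.0][i])[0]
            for i in range(rset.n_subjects)
        ]
        assert np.nanmean(accs) > 0.9
        dev_orig = response_deviation(rset.data).response_deviation
        dev_aligned = response_deviation(res.aligned).response_deviation
        assert dev_aligned < dev_orig

    def test_two_passes_change_average_less_than_first(self, noiseless_sim):
        # structural-average idempotence: the pass-2 update is small compared
        # with the pass-1 alignment gain
        rset = noiseless_sim.as_response_set(with_replicates=False)
        cfg = LossConfig("psdd", 0.0)
        one = register_at(rset, cfg, n_passes=1)
        two = register_at(rset, cfg, n_passes=2)
        original_avg = rset.data[0.0].mean(axis=1)
        gain1 = np.linalg.norm(one.structural_avg[0.0] - original_avg)
        update2 = np.linalg.norm(two.structural_avg[0.0] - one.structural_avg[0.0])
        assert update2 < gain1

    def test_alignment_never_degrades_fitted_objective(self, noiseless_sim):
        rset = noiseless_sim.as_response_set(with_replicates=False)
        res = register_at(rset, LossConfig("psd", 0.01))
        # diagnostics carry (cond, subject, final_loss, converged)
        assert len(res.fit_diagnostics) == 2 * rset.n_subjects

    def test_missing_target_condition_rejected(self, window, template):
        with pytest.raises(ValueError):
            ResponseSet(window=window, subjects=[0, 1],
                        data={"bb": np.column_stack([template.samples] * 2)},
                        target_condition="nope")


class TestRegisterPw:
    def test_two_subjects_use_single_pairwise_warp(self, window, template, rng):
        h0 = build_warp(rng.uniform(-0.3, 0.3, 13), window)
        x2 = warp_response(template.samples, invert_warp(h0))
        rset = ResponseSet(
            window=window, subjects=["a", "b"],
            data={"bb": np.column_stack([template.samples, x2])},
            target_condition="bb",
        )
        res = register_pw(rset, LossConfig("psdd", 0.0))
        direct = fit_warp(template.samples, x2, LossConfig("psdd", 0.0), window=window)
        assert np.allclose(res.warps["bb"][0].values, direct.warp.values)

    def test_identical_subjects_average_to_identity(self, window, template):
        rset = _identical_subject_set(window, template, n=3)
        res = register_pw(rset, LossConfig("psdd", 0.0))
        for w in res.warps["bb"]:
            assert np.max(np.abs(w.values - w.grid)) < 0.01

    def test_averaged_warps_stay_monotone_and_pinned(self, noiseless_sim):
        rset = noiseless_sim.as_response_set(with_replicates=False)
        res = register_pw(rset, LossConfig("psdd", 0.0))
        for w in res.warps[0.0]:
            assert np.all(np.diff(w.values) > 0)
            assert w.values[0] == pytest.approx(0.0, abs=1e-12)
            assert w.values[-1] == pytest.approx(1.0, abs=1e-12)

    def test_single_subject_rejected(self, window, template):
        rset = ResponseSet(
            window=window, subjects=["solo"],
            data={"bb": template.samples[:, None]}, target_condition="bb",
        )
        with pytest.raises(ValueError):
            register_pw(rset, LossConfig("psd", 0.0))


@pytest.fixture(scope="module")
def replicate_sim():
    return simulate_dataset(n_subjects=5, warp_magnitude=0.3,
                            dsnr_grid=[-15.0], seed=3)


class TestWarpReplicates:
    def test_identical_replicates_make_same_equal_cross(self, window, template):
        n = 3
        data = {"bb": np.column_stack([template.samples] * n)}
        rset = ResponseSet(
            window=window, subjects=list(range(n)), data=data,
            target_condition="bb",
            replicates={"bb": (data["bb"].copy(), data["bb"].copy())},
        )
        reps = warp_replicates(rset, LossConfig("psdd", 0.0))
        assert np.allclose(reps.same11["bb"], reps.cross21["bb"])
        assert np.allclose(reps.same22["bb"], reps.cross12["bb"])

    def test_noisy_replicates_show_noise_alignment_under_greedy_config(self, replicate_sim):
        from abrwarp.validation import replicate_deviations

        rset = replicate_sim.as_response_set()
        out = replicate_deviations(warp_replicates(rset, LossConfig("psd", 0.0)))
        # warps fitted on one replicate align its own noise, not the other's
        assert out["sd_cross"] > out["sd_same"]

    def test_missing_replicates_rejected(self, window, template):
        rset = _identical_subject_set(window, template)
        with pytest.raises(ValueError):
            warp_replicates(rset, LossConfig("psd", 0.0))


def test_register_dispatches_and_rejects_unknown_procedure(noiseless_sim):
    rset = noiseless_sim.as_response_set(with_replicates=False)
    with pytest.raises(ValueError):
        register(rset, LossConfig("psd", 0.0), "xx")
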