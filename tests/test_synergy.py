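"""MeanR/MaxR statistics, Cp bootstrap and the full analysis pipeline."""

import dataclasses

import numpy as np
import pytest

from genloewe import (
    AnalysisConfig,
    MarginalCurve,
    compute_deviations,
    estimate_cp_bootstrap,
    fit_marginals,
    generate_board,
    maxR_test,
    meanR_test,
    predict_surface,
    run_synergy_analysis,
)
from genloewe.boards import Checkerboard
from genloewe.simulate import default_spec
from genloewe.synergy import OffAxisDeviations

import pandas as pd


def make_dev(d, sigma2=0.01, n_reps=1, df=8):
    d = np.asarray(d, dtype=float)
    k = len(d)
    doses = np.column_stack([np.arange(1.0, k + 1), np.arange(1.0, k + 1)])
    return OffAxisDeviations(
        doses=doses,
        observed_mean=0.5 + d,
        predicted=np.full(k, 0.5),
        n_reps=np.full(k, n_reps, dtype=int),
        sigma2=sigma2,
        df_residual=df,
    )


class TestComputeDeviations:
    def test_replicate_mean_contrast(self, agonist_pair):
        df = pd.DataFrame(
            {
                "d1": [1.0, 0.0, 1.0, 1.0, 0.0, 2.0, 4.0, 0.0, 0.0, 0.0],
                "d2": [0.0, 5.0, 2.0, 2.0, 10.0, 0.0, 0.0, 20.0, 40.0, 0.0],
                "effect": [0.5, 0.2, 0.4, 0.6, 0.3, 0.7, 0.8, 0.35, 0.4, 0.1],
            }
        )
        board = Checkerboard.from_dataframe(df)
        fit_stub = fit_stub_from(agonist_pair, sigma2=0.01, df_resid=5)
        surface = predict_surface(agonist_pair, board.off_axis_grid())
        surface = dataclasses.replace(surface, predicted=np.array([0.3]))
        dev = compute_deviations(board, surface, fit_stub)
        assert len(dev) == 1
        assert dev.n_reps.tolist() == [2]
        assert dev.deviations[0] == pytest.approx(0.5 - 0.3)
        assert dev.sigma2 == 0.01 and dev.df_residual == 5

    def test_mismatched_surface_rejected(self, agonist_pair):
        spec = default_spec(seed=3)
        board = generate_board(spec)
        fit = fit_marginals(board.mono_data())
        surface = predict_surface(fit.curves, board.off_axis_grid()[:-1])
        with pytest.raises(ValueError):
            compute_deviations(board, surface, fit)


def fit_stub_from(curves, sigma2, df_resid):
    from genloewe.marginals import MarginalFitResult

    return MarginalFitResult(
        curves=tuple(curves),
        sigma2=sigma2,
        df_residual=df_resid,
        se_log_ec50=(0.1, 0.1),
        covariance=np.eye(7),
        n_obs=df_resid + 7,
        converged=True,
    )


@pytest.fixture(scope="module")
def noisy_setup():
    spec = default_spec(seed=11)
    board = generate_board(spec)
    fit = fit_marginals(board.mono_data())
    return board.mono_data(), fit, board.off_axis_grid()


class TestCpBootstrap:
    def test_zero_residual_variance_gives_zero_cp(self, agonist_pair):
        spec = default_spec(seed=5, noise_sd=0.0)
        board = generate_board(spec)
        fit = fit_marginals(board.mono_data())
        cp = estimate_cp_bootstrap(board.mono_data(), fit, board.off_axis_grid(), n_boot=10, seed=0)
        assert np.max(np.abs(cp)) < 1e-12

    def test_symmetric_psd_with_nonnegative_diagonal(self, noisy_setup):
        mono, fit, grid = noisy_setup
        cp = estimate_cp_bootstrap(mono, fit, grid, n_boot=30, seed=1)
        np.testing.assert_allclose(cp, cp.T)
        assert np.all(np.diag(cp) >= 0)
        assert np.min(np.linalg.eigvalsh(cp)) > -1e-12

    def test_deterministic_given_seed(self, noisy_setup):
        mono, fit, grid = noisy_setup
        cp1 = estimate_cp_bootstrap(mono, fit, grid, n_boot=20, seed=42)
        cp2 = estimate_cp_bootstrap(mono, fit, grid, n_boot=20, seed=42)
        np.testing.assert_array_equal(cp1, cp2)

    def test_monte_carlo_convergence(self, noisy_setup):
        # element-wise error vs a 10x larger reference run shrinks with n_boot
        mono, fit, grid = noisy_setup
        ref = estimate_cp_bootstrap(mono, fit, grid, n_boot=1500, seed=7)
        err_small = np.max(np.abs(estimate_cp_bootstrap(mono, fit, grid, n_boot=15, seed=8) - ref))
        err_large = np.max(np.abs(estimate_cp_bootstrap(mono, fit, grid, n_boot=150, seed=9) - ref))
        assert err_large < err_small


class TestMeanR:
    def test_zero_deviation_is_null(self):
        dev = make_dev(np.zeros(5))
        cp = np.zeros((5, 5))
        for method in ("parametric", "bootstrap"):
            res = meanR_test(dev, cp, null_method=method, n_boot_null=99, seed=1)
            assert res.statistic == pytest.approx(0.0, abs=1e-12)
            assert res.pvalue == pytest.approx(1.0, abs=0.02)

    def test_parametric_pvalue_monotone_in_statistic(self):
        cp = np.zeros((4, 4))
        stats, ps = [], []
        for scale in (0.02, 0.1, 0.4):
            res = meanR_test(make_dev(np.full(4, scale)), cp, null_method="parametric")
            stats.append(res.statistic)
            ps.append(res.pvalue)
        assert stats == sorted(stats)
        assert ps == sorted(ps, reverse=True)

    def test_bootstrap_seeded_determinism(self):
        dev = make_dev([0.05, -0.02, 0.1, 0.0])
        cp = 1e-4 * np.eye(4)
        r1 = meanR_test(dev, cp, null_method="bootstrap", n_boot_null=300, seed=123)
        r2 = meanR_test(dev, cp, null_method="bootstrap", n_boot_null=300, seed=123)
        r3 = meanR_test(dev, cp, null_method="bootstrap", n_boot_null=300, seed=124)
        assert r1.pvalue == r2.pvalue
        assert r1.pvalue != r3.pvalue

    def test_parametric_and_bootstrap_agree_on_replicated_board(self):
        spec = default_spec(seed=21, n_reps=3)
        board = generate_board(spec)
        res_p = run_synergy_analysis(
            board, AnalysisConfig(null_method="parametric", n_boot_cp=60, seed=21)
        )
        res_b = run_synergy_analysis(
            board, AnalysisConfig(null_method="bootstrap", n_boot_null=1500, n_boot_cp=60, seed=21)
        )
        assert res_p.meanR.pvalue == pytest.approx(res_b.meanR.pvalue, abs=0.15)


class TestMaxR:
    def test_all_zero_deviations_no_calls(self):
        dev = make_dev(np.zeros(6))
        res = maxR_test(dev, np.zeros((6, 6)), null_method="bootstrap", n_boot_null=99, seed=0)
        assert res.pvalue == pytest.approx(1.0, abs=0.02)
        assert all(call == "additive" for call in res.calls)

    @pytest.mark.parametrize("sign, expected", [(-1.0, "synergy"), (1.0, "antagonism")])
    def test_single_spike_called_with_direction(self, sign, expected):
        d = np.zeros(9)
        d[4] = sign * 0.8  # 8 residual SDs at sigma2 = 0.01
        dev = make_dev(d)
        res = maxR_test(dev, np.zeros((9, 9)), null_method="parametric", n_boot_null=2000, seed=5)
        assert res.calls[4] == expected
        assert all(call == "additive" for i, call in enumerate(res.calls) if i != 4)
        assert res.pvalue < 0.01

    def test_increasing_effect_convention_flips_direction(self):
        d = np.zeros(9)
        d[2] = 0.8
        dev = make_dev(d)
        res = maxR_test(
            dev, np.zeros((9, 9)), null_method="parametric", n_boot_null=2000, seed=5,
            decreasing_effect=False,
        )
        assert res.calls[2] == "synergy"

    def test_calls_consistent_with_shared_threshold(self):
        rng = np.random.default_rng(3)
        dev = make_dev(rng.normal(0, 0.12, 12))
        res = maxR_test(dev, np.zeros((12, 12)), null_method="bootstrap", n_boot_null=500, seed=9)
        flagged = {i for i, c in enumerate(res.calls) if c != "additive"}
        exceed = {i for i, t in enumerate(res.t_values) if abs(t) > res.threshold}
        assert flagged == exceed


class TestPipeline:
    def test_noiseless_sham_board_is_additive(self):
        curve = MarginalCurve(b=0.1, m=1.0, ec50=1.0, hill=1.0)
        spec = default_spec(curves=(curve, curve), doses2=2.0 ** np.arange(-3.0, 4.0),
                            noise_sd=0.0, seed=0)
        res = run_synergy_analysis(generate_board(spec), AnalysisConfig(seed=0, n_boot_cp=5))
        assert res.status == "ok"
        assert res.overall_call == "additive"
        assert res.meanR.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.meanR.pvalue == 1.0

    def test_qc_failure_invalidates_without_testing(self):
        board = generate_board(default_spec(seed=2))
        res = run_synergy_analysis(board, AnalysisConfig(qc_threshold=1e-6, seed=2))
        assert res.status == "invalidated"
        assert res.overall_call == "invalidated"
        assert res.meanR is None and res.maxR is None
        assert res.qc.reasons

    def test_injected_synergy_detected_with_direction(self):
        spec = default_spec(seed=8, deviation=-0.2)  # strong extra effect, decreasing readout
        res = run_synergy_analysis(
            generate_board(spec),
            AnalysisConfig(null_method="bootstrap", n_boot_null=300, n_boot_cp=50, seed=8),
        )
        assert res.status == "ok"
        assert res.meanR.pvalue <= 0.05
        assert res.overall_call == "synergy"

    def test_auto_null_selection_follows_replicates(self):
        res1 = run_synergy_analysis(
            generate_board(default_spec(seed=4)), AnalysisConfig(n_boot_null=50, n_boot_cp=20, seed=4)
        )
        res3 = run_synergy_analysis(
            generate_board(default_spec(seed=4, n_reps=3)),
            AnalysisConfig(n_boot_null=50, n_boot_cp=20, seed=4),
        )
        assert res1.null_method == "bootstrap"
        assert res3.null_method == "parametric"

    def test_seeded_determinism_of_full_json(self):
        board = generate_board(default_spec(seed=6))
        cfg = AnalysisConfig(n_boot_null=100, n_boot_cp=30, seed=77)
        j1 = run_synergy_analysis(board, cfg).to_json()
        j2 = run_synergy_analysis(board, cfg).to_json()
        assert j1 == j2
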