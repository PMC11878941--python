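"""Weibull MLE fitting, the 72.5% criterion and DRT extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

import rdklearn as rk
from rdklearn.psychometric import (
    LevelCounts,
    WeibullThreshold,
    _negloglik,
    aggregate,
    criterion,
    drt,
    fit_weibull,
    psychometric_p,
)


class TestCriterion:
    def test_component_judgment_value(self):
        assert criterion(0.5, 0.05) == pytest.approx(0.725, abs=1e-12)

    @pytest.mark.parametrize(
        "gamma, lapse, expected", [(0.25, 0.05, 0.60), (0.5, 0.0, 0.75)]
    )
    def test_general_midpoint(self, gamma, lapse, expected):
        assert criterion(gamma, lapse) == pytest.approx(expected)

    @pytest.mark.parametrize("gamma, lapse", [(0.8, 0.3), (-0.1, 0.05), (0.5, 1.2)])
    def test_domain_errors(self, gamma, lapse):
        with pytest.raises(ValueError):
            criterion(gamma, lapse)


class TestDRT:
    @pytest.mark.parametrize(
        "alpha, beta, expected",
        [
            (200.0, 2.0, 200.0 * np.sqrt(np.log(2))),  # ~166.51
            (200.0, 1.0, 200.0 * np.log(2)),  # ~138.63
        ],
    )
    def test_closed_form(self, alpha, beta, expected):
        fit = rk.PsychometricFit(alpha, beta, 0.5, 0.05, 0.0, True, np.nan)
        assert drt(fit) == pytest.approx(expected, abs=1e-9)

    def test_psi_at_threshold_is_criterion(self):
        fit = rk.PsychometricFit(137.0, 3.3, 0.5, 0.05, 0.0, True, np.nan)
        assert psychometric_p(drt(fit), 137.0, 3.3, 0.5, 0.05) == pytest.approx(0.725)

    @pytest.mark.parametrize("alpha", [10.0, 50.0, 160.0, 400.0])
    @pytest.mark.parametrize("beta", [0.5, 1.0, 2.0, 6.0])
    def test_closed_form_matches_numeric_root(self, alpha, beta):
        """Numeric inversion of psi agrees with alpha*(ln 2)^(1/beta) to 1e-6."""
        closed = alpha * np.log(2.0) ** (1.0 / beta)
        numeric = brentq(
            lambda r: psychometric_p(r, alpha, beta, 0.5, 0.05) - 0.725,
            1e-9,
            1e5,
            xtol=1e-10,
        )
        assert numeric == pytest.approx(closed, abs=1e-6)

    def test_non_converged_fit_rejected(self):
        fit = rk.PsychometricFit(np.nan, np.nan, 0.5, 0.05, np.nan, False, np.nan)
        with pytest.raises(ValueError):
            drt(fit)


class TestAggregate:
    def test_counts_per_level(self):
        df = pd.DataFrame(
            {
                "direction_range_deg": [80.0, 80.0, 80.0, 160.0],
                "v_correct": [True, True, False, True],
                "h_correct": [True, False, False, True],
                "combined_correct": [True, False, False, True],
                "aborted": [False, False, False, False],
            }
        )
        counts = aggregate(df, "vertical")
        assert counts.range_deg.tolist() == [80.0, 160.0]
        assert counts.n_trials.tolist() == [3, 1]
        assert counts.n_correct.tolist() == [2, 1]

    def test_combined_counts_require_both_components(self):
        df = pd.DataFrame(
            {
                "direction_range_deg": [80.0] * 3,
                "v_correct": [True, True, False],
                "h_correct": [True, False, True],
                "combined_correct": [True, False, False],
                "aborted": [False] * 3,
            }
        )
        counts = aggregate(df, "combined")
        assert counts.n_correct.tolist() == [1]

    def test_aborted_rows_excluded(self):
        df = pd.DataFrame(
            {
                "direction_range_deg": [80.0, 80.0],
                "v_correct": [True, None],
                "h_correct": [True, None],
                "combined_correct": [True, None],
                "aborted": [False, True],
            }
        )
        assert aggregate(df, "vertical").n_trials.tolist() == [1]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate(pd.DataFrame(columns=["direction_range_deg", "v_correct"]))


class TestFitWeibull:
    def test_parameter_recovery_large_n(self):
        """Counts from alpha=160, beta=2 at 500 trials/level recover alpha
        within 5% (fixed-seed simulation oracle)."""
        rng = np.random.default_rng(1)
        n = np.full(10, 500)
        p = psychometric_p(rk.LEVEL_GRID, 160.0, 2.0)
        counts = LevelCounts(rk.LEVEL_GRID, n, rng.binomial(n, p))
        fit = fit_weibull(counts)
        assert fit.converged
        assert fit.alpha == pytest.approx(160.0, rel=0.05)
        assert fit.drt_deg == pytest.approx(fit.threshold())

    def test_all_correct_is_degenerate(self):
        counts = LevelCounts(rk.LEVEL_GRID, np.full(10, 20), np.full(10, 20))
        assert not fit_weibull(counts).converged

    def test_single_level_is_underdetermined(self):
        counts = LevelCounts([160.0], [100], [70])
        assert not fit_weibull(counts).converged

    def test_zero_trial_levels_dropped(self):
        counts = LevelCounts([0.0, 160.0, 320.0], [50, 0, 50], [47, 0, 26])
        fit = fit_weibull(counts)
        assert fit.converged

    def test_invalid_gamma_lapse_raise(self):
        counts = LevelCounts([0.0, 160.0], [50, 50], [45, 30])
        with pytest.raises(ValueError):
            fit_weibull(counts, gamma=0.9, lapse=0.3)

    def test_optimum_beats_coarse_grid(self):
        """Likelihood at the optimizer's solution >= every point of a coarse
        brute-force (alpha, beta) grid (independent oracle)."""
        rng = np.random.default_rng(3)
        n = np.full(10, 60)
        p = psychometric_p(rk.LEVEL_GRID, 140.0, 1.5)
        k = rng.binomial(n, p)
        counts = LevelCounts(rk.LEVEL_GRID, n, k)
        fit = fit_weibull(counts)
        grid_nll = min(
            _negloglik(
                np.log([a, b]), counts.range_deg, n, k, 0.5, 0.05
            )
            for a in np.geomspace(20, 1000, 40)
            for b in np.geomspace(0.3, 8, 30)
        )
        assert -fit.loglik <= grid_nll + 1e-6

    def test_threshold_ordering_preserved(self):
        """Higher true DRT => stochastically higher fitted DRT (rank corr > 0.9)."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(11)
        true_alphas = np.linspace(80, 280, 12)
        fitted = []
        for a in true_alphas:
            p = psychometric_p(rk.LEVEL_GRID, a, 2.0)
            n = np.full(10, 120)
            fit = fit_weibull(LevelCounts(rk.LEVEL_GRID, n, rng.binomial(n, p)))
            fitted.append(fit.drt_deg)
        rho = spearmanr(true_alphas, fitted).statistic
        assert rho > 0.9


class TestWeibullThresholdEstimator:
    def test_fit_from_trialwise_data(self):
        rng = np.random.default_rng(5)
        r = np.repeat(rk.LEVEL_GRID, 200)
        y = rng.random(len(r)) < psychometric_p(r, 180.0, 2.0)
        est = WeibullThreshold().fit(r, y)
        assert est.converged_
        assert est.drt_ == pytest.approx(180.0 * np.sqrt(np.log(2)), rel=0.08)
        proba = est.predict_proba([0.0, 355.0])
        assert proba.shape == (2, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_get_params_roundtrip(self):
        est = WeibullThreshold(gamma=0.25)
        assert est.get_params()["gamma"] == 0.25
        est.set_params(lapse=0.02)
        assert est.lapse == 0.02

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = clone(WeibullThreshold(gamma=0.25, lapse=0.01))
        assert est.gamma == 0.25 and est.lapse == 0.01
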