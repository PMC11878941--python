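"""Simulated observers: psychometric function, parametric and mechanistic."""

import numpy as np
import pytest

from rdklearn.observer import (
    MechanisticObserver,
    ObserverParams,
    ParametricObserver,
    PerceptReport,
    psychometric_p,
    respond_mechanistic,
    respond_parametric,
)
from rdklearn.stimulus import (
    LEVEL_GRID,
    TrialStimulus,
    component_truth,
    sample_dot_directions,
    score_response,
    StimulusSpec,
)


class TestPsychometricP:
    def test_zero_range_hits_lapse_ceiling(self):
        assert psychometric_p(0.0, 160.0, 2.0, 0.5, 0.05) == pytest.approx(0.95)

    def test_value_at_alpha(self):
        # psi(alpha) = gamma + (1-gamma-lapse)/e, independent of beta
        expected = 0.5 + 0.45 / np.e
        for beta in (0.7, 1.0, 2.0, 5.0):
            assert psychometric_p(160.0, 160.0, beta, 0.5, 0.05) == pytest.approx(expected)

    def test_asymptote_is_chance(self):
        assert psychometric_p(100 * 160.0, 160.0, 2.0, 0.5, 0.0) == pytest.approx(
            0.5, abs=1e-10
        )

    def test_monotone_non_increasing(self):
        r = np.linspace(0, 400, 200)
        p = psychometric_p(r, 123.0, 1.7)
        assert np.all(np.diff(p) <= 0)

    @pytest.mark.parametrize("alpha, beta", [(0.0, 2.0), (-1.0, 2.0), (100.0, 0.0)])
    def test_invalid_parameters_rejected(self, alpha, beta):
        with pytest.raises(ValueError):
            psychometric_p(100.0, alpha, beta)


class TestObserverParams:
    def test_cue_reliability_defaults_to_one_minus_lapse(self):
        assert ObserverParams(lapse=0.05).effective_cue_reliability == pytest.approx(0.95)

    def test_zero_transfer_freezes_untrained_alpha(self):
        obs = ObserverParams(alpha_v_deg=200.0, learn_rate_v=5.0, transfer_v=0.0)
        assert obs.effective_alpha("v", 10, "untrained", 0.0) == pytest.approx(200.0)
        assert obs.effective_alpha("v", 10, "trained", 0.0) == pytest.approx(245.0)

    def test_noise_attenuates_alpha(self):
        obs = ObserverParams(alpha_v_deg=200.0, noise_exponent=1.0)
        assert obs.effective_alpha("v", 1, "trained", 0.3) == pytest.approx(140.0)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            ObserverParams(lapse=0.5)

    def test_aborted_report_carries_no_response(self):
        with pytest.raises(ValueError):
            PerceptReport(component_truth(45), aborted=True)


class TestParametricObserver:
    def test_perfect_cue_makes_horizontal_always_correct(self, rng):
        obs = ObserverParams(av_cue=True, cue_reliability=1.0, lapse=0.0)
        trial = TrialStimulus.from_level(135, 9, 0.0)
        truth = component_truth(135)
        for _ in range(200):
            rep = respond_parametric(obs, trial, 1, rng, cue_present=True)
            assert score_response(truth, rep.response)[1]  # horizontal correct

    def test_marginal_correctness_matches_psychometric_p(self, rng):
        """Empirical component correctness tracks the analytic Weibull (3 sigma)."""
        obs = ObserverParams(alpha_h_deg=150.0, alpha_v_deg=150.0, beta=2.0)
        trial = TrialStimulus.from_level(45, 4, 0.0)  # R = 160
        truth = component_truth(45)
        n = 10_000
        v_hits = h_hits = 0
        for _ in range(n):
            rep = respond_parametric(obs, trial, 1, rng)
            _, h, v = score_response(truth, rep.response)
            v_hits += v
            h_hits += h
        p = psychometric_p(160.0, 150.0, 2.0, 0.5, 0.05)
        tol = 3 * np.sqrt(p * (1 - p) / n)
        assert abs(v_hits / n - p) < tol
        assert abs(h_hits / n - p) < tol

    def test_easy_stimulus_correctness_near_ceiling(self, rng):
        """Very large alpha: correctness ~ 1 - lapse within binomial 3 sigma."""
        obs = ObserverParams(alpha_v_deg=1e6, alpha_h_deg=1e6, lapse=0.05)
        trial = TrialStimulus.from_level(315, 9, 0.0)
        truth = component_truth(315)
        n = 10_000
        hits = sum(
            score_response(truth, respond_parametric(obs, trial, 1, rng).response)[2]
            for _ in range(n)
        )
        assert abs(hits / n - 0.95) < 3 * np.sqrt(0.95 * 0.05 / n)

    def test_components_independent_without_cue(self, rng):
        """P(combined) ~ P(h) * P(v) when no auditory cue is present."""
        obs = ObserverParams(alpha_h_deg=120.0, alpha_v_deg=180.0)
        trial = TrialStimulus.from_level(225, 5, 0.0)
        truth = component_truth(225)
        n = 20_000
        res = np.array(
            [
                score_response(truth, respond_parametric(obs, trial, 1, rng).response)
                for _ in range(n)
            ],
            dtype=float,
        )
        p_c, p_h, p_v = res.mean(axis=0)
        assert p_c == pytest.approx(p_h * p_v, abs=4 * np.sqrt(0.25 / n) * 3)

    def test_abort_probability_honored(self, rng):
        obs = ObserverParams(abort_prob=0.2)
        trial = TrialStimulus.from_level(45, 2, 0.0)
        n = 5000
        aborts = sum(respond_parametric(obs, trial, 1, rng).aborted for _ in range(n))
        assert abs(aborts / n - 0.2) < 3 * np.sqrt(0.2 * 0.8 / n)

    def test_session_day_must_be_positive(self, rng):
        with pytest.raises(ValueError):
            respond_parametric(ObserverParams(), TrialStimulus.from_level(45, 0, 0.0), 0, rng)


class TestMechanisticObserver:
    def test_coherent_stimulus_high_kappa_always_upper_right(self, rng):
        dirs = np.full(100, 45.0)
        for _ in range(50):
            rep = respond_mechanistic(1e6, dirs, rng)
            assert rep.response == component_truth(45)

    def test_pure_noise_gives_uniform_quadrants(self, rng):
        """All-noise dots: the four quadrant responses are equiprobable."""
        from scipy.stats import chisquare

        spec = StimulusSpec()
        trial = TrialStimulus.from_level(45, 5, 1.0)
        counts = {}
        for _ in range(4000):
            dirs = sample_dot_directions(spec, trial, rng)
            rep = respond_mechanistic(4.0, dirs, rng)
            counts[rep.response] = counts.get(rep.response, 0) + 1
        assert chisquare(list(counts.values())).pvalue > 0.01

    def test_empty_input_rejected(self, rng):
        with pytest.raises(ValueError):
            respond_mechanistic(4.0, np.array([]), rng)

    def test_proportion_correct_non_increasing_in_range(self, rng):
        """Monte-Carlo psychometric curve over the level grid is monotone
        non-increasing (within sampling slack)."""
        spec = StimulusSpec()
        observer = MechanisticObserver(kappa=6.0)
        p_correct = []
        for level in range(len(LEVEL_GRID)):
            trial = TrialStimulus.from_level(45, level, 0.2)
            truth = component_truth(45)
            hits = 0
            n = 600
            for _ in range(n):
                dirs = sample_dot_directions(spec, trial, rng)
                rep = observer.respond(dirs, rng)
                hits += score_response(truth, rep.response)[0]
            p_correct.append(hits / n)
        p = np.array(p_correct)
        # allow binomial jitter between adjacent levels but demand global decline
        assert np.all(np.diff(p) < 0.08)
        assert p[0] > p[-1] + 0.2
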