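"""Synchronization metrics and gain estimators."""

import math

import numpy as np
import pytest

from adamsync import (
    AdaptParams,
    AgentSpec,
    DyadRecord,
    NoiseParams,
    ValidationError,
    asynchrony_stats,
    estimate_alpha_ar,
    estimate_pcr,
    fit_params_gridsearch,
    gen_isochronous,
    gen_sinusoidal_tempo,
    gen_step_tempo,
    interval_cc,
    pt_ratio,
    run_perturbation_trial,
    simulate_unidirectional,
)
from adamsync.timing import IntervalSeries


def _record_from_onsets(partner, adam):
    partner = np.asarray(partner, float)
    adam = np.asarray(adam, float)
    return DyadRecord(
        partner_onsets_ms=partner,
        adam_onsets_ms=adam,
        asynchronies_ms=partner - adam,
        timekeeper_ms=np.full(partner.size, 500.0),
        mechanism=["initial"] + ["adaptation"] * (partner.size - 1),
    )


class TestAsynchronyStats:
    def test_constant_asynchrony(self):
        rec = _record_from_onsets([0, 500, 1000], [10, 510, 1010])
        rep = asynchrony_stats(rec)
        assert rep.mean_asyn_ms == pytest.approx(-10.0)
        assert rep.sd_asyn_ms == 0.0

    def test_perfect_synchrony(self):
        onsets = np.arange(5) * 500.0
        rep = asynchrony_stats(_record_from_onsets(onsets, onsets))
        assert rep.mean_asyn_ms == 0.0
        assert rep.sd_asyn_ms == 0.0

    def test_motor_noise_sets_the_asynchrony_floor(self):
        stimulus = gen_isochronous(500, 10_000)
        agent = AgentSpec(
            adapt=AdaptParams(alpha=1.0),
            noise=NoiseParams(sigma_motor=5.0, seed=13),
            base_period_ms=500.0,
        )
        rep = asynchrony_stats(simulate_unidirectional(stimulus, agent))
        assert rep.sd_asyn_ms == pytest.approx(5.0, rel=0.10)

    def test_too_short_record_rejected(self):
        with pytest.raises(ValidationError):
            asynchrony_stats(_record_from_onsets([0, 500], [0, 500]), warmup=1)


class TestIntervalCrossCorrelation:
    def test_self_correlation_is_one(self):
        x = IntervalSeries(500 + 50 * np.sin(np.arange(40) / 3))
        assert interval_cc(x, x, [0])[0] == pytest.approx(1.0)

    def test_pure_tracking_peaks_at_lag_one(self):
        y = IntervalSeries(500 + 50 * np.sin(np.arange(40) / 3))
        x = IntervalSeries(np.concatenate([[500.0], y.intervals[:-1]]))
        assert interval_cc(x, y, [1])[1] == pytest.approx(1.0)

    def test_constant_series_is_undefined(self):
        y = IntervalSeries(500 + 50 * np.sin(np.arange(40) / 3))
        x = IntervalSeries(np.full(40, 500.0))
        assert math.isnan(interval_cc(x, y, [0])[0])

    def test_swap_symmetry_with_negated_lag(self):
        rng = np.random.default_rng(2)
        x = IntervalSeries(500 + rng.normal(0, 10, 60))
        y = IntervalSeries(500 + rng.normal(0, 10, 60))
        for lag in (0, 1, 2):
            assert interval_cc(x, y, [lag])[lag] == pytest.approx(
                interval_cc(y, x, [-lag])[-lag]
            )

    def test_coefficients_bounded(self):
        rng = np.random.default_rng(3)
        x = IntervalSeries(500 + rng.normal(0, 10, 50))
        y = IntervalSeries(500 + rng.normal(0, 10, 50))
        for lag, c in interval_cc(x, y, [-2, -1, 0, 1, 2]).items():
            assert -1.0 <= c <= 1.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            interval_cc(
                IntervalSeries(np.full(10, 500.0)),
                IntervalSeries(np.full(11, 500.0)),
                [0],
            )


class TestPredictionTrackingRatio:
    @staticmethod
    def _sinusoid(n=100):
        return 500 + 50 * np.sin(2 * np.pi * np.arange(n) / 20)

    def test_identical_series_classify_as_predictor(self):
        y = IntervalSeries(self._sinusoid())
        ratio = pt_ratio(IntervalSeries(self._sinusoid()), y)
        assert ratio > 1.0

    def test_lagged_copy_classifies_as_tracker(self):
        yv = self._sinusoid()
        x = IntervalSeries(np.concatenate([[500.0], yv[:-1]]))
        ratio = pt_ratio(x, IntervalSeries(yv))
        assert ratio < 1.0

    def test_undefined_when_lag_one_not_positive(self):
        rng = np.random.default_rng(4)
        x = IntervalSeries(500 + rng.normal(0, 10, 30))
        y = IntervalSeries(500 + rng.normal(0, 10, 30))
        cc = interval_cc(x, y, [1])
        if cc[1] <= 0:
            assert math.isnan(pt_ratio(x, y))

    def test_anticipatory_agent_is_a_predictor_and_mimic_is_a_tracker(self):
        from adamsync import AnticipParams

        stimulus = gen_sinusoidal_tempo(500, 50, 20, 200)
        ratios = {}
        for w in (0.0, 1.0):
            agent = AgentSpec(
                adapt=AdaptParams(alpha=1.0),
                anticip=AnticipParams(k=3, mimic_weight=w),
                base_period_ms=500.0,
            )
            rec = simulate_unidirectional(stimulus, agent, n_warmup=4)
            ratios[w] = pt_ratio(
                IntervalSeries(np.diff(rec.adam_onsets_ms[4:])),
                IntervalSeries(np.diff(rec.partner_onsets_ms[4:])),
            )
        assert ratios[0.0] > 1.0
        assert ratios[1.0] < 1.0


class TestAlphaEstimation:
    def test_ar_estimate_is_exact_on_noise_free_decay(self):
        agent = AgentSpec(adapt=AdaptParams(alpha=0.5), base_period_ms=500.0)
        rec = run_perturbation_trial(500, 200, 50, 30.0, agent)
        # regress on the free decay from the perturbation onward; the jump
        # into the perturbation cycle is not part of the AR(1) recursion
        assert estimate_alpha_ar(rec, warmup=51) == pytest.approx(0.5, abs=1e-9)

    def test_ar_estimate_recovers_gain_under_timekeeper_noise(self):
        stimulus = gen_isochronous(500, 5000)
        agent = AgentSpec(
            adapt=AdaptParams(alpha=0.4),
            noise=NoiseParams(sigma_timekeeper=10.0, seed=3),
            base_period_ms=500.0,
        )
        rec = simulate_unidirectional(stimulus, agent)
        assert estimate_alpha_ar(rec) == pytest.approx(0.4, abs=0.05)

    def test_full_correction_whitens_the_asynchronies(self):
        stimulus = gen_isochronous(500, 5000)
        agent = AgentSpec(
            adapt=AdaptParams(alpha=1.0),
            noise=NoiseParams(sigma_timekeeper=10.0, seed=8),
            base_period_ms=500.0,
        )
        rec = simulate_unidirectional(stimulus, agent)
        assert estimate_alpha_ar(rec) == pytest.approx(1.0, abs=0.05)

    def test_ar_and_gridsearch_agree_on_phase_only_data(self):
        stimulus = gen_isochronous(500, 5000)
        agent = AgentSpec(
            adapt=AdaptParams(alpha=0.6),
            noise=NoiseParams(sigma_timekeeper=10.0, seed=21),
            base_period_ms=500.0,
        )
        rec = simulate_unidirectional(stimulus, agent)
        ar = estimate_alpha_ar(rec)
        grid = fit_params_gridsearch(
            rec, agent, np.round(np.arange(0.3, 0.91, 0.05), 10), [0.0],
            n_sims=10, seed=2,
        )
        assert abs(ar - grid.alpha) <= 0.05


class TestGridSearch:
    def test_singleton_grid_returns_that_point(self):
        stimulus = gen_isochronous(500, 120)
        agent = AgentSpec(
            adapt=AdaptParams(alpha=0.5),
            noise=NoiseParams(sigma_timekeeper=5.0, seed=1),
            base_period_ms=500.0,
        )
        rec = simulate_unidirectional(stimulus, agent)
        res = fit_params_gridsearch(rec, agent, [0.5], [0.0], n_sims=3, seed=0)
        assert (res.alpha, res.beta) == (0.5, 0.0)

    def test_noise_free_observation_has_zero_loss_at_truth(self):
        stimulus = gen_step_tempo(500, 470, 20, 120)
        agent = AgentSpec(adapt=AdaptParams(alpha=0.5, beta=0.1), base_period_ms=500.0)
        rec = simulate_unidirectional(stimulus, agent)
        res = fit_params_gridsearch(
            rec, agent, [0.3, 0.5, 0.7], [0.0, 0.1], n_sims=2, seed=0
        )
        assert (res.alpha, res.beta) == (0.5, 0.1)
        assert res.loss == pytest.approx(0.0, abs=1e-12)

    def test_divergent_grid_points_get_infinite_loss(self):
        stimulus = gen_isochronous(500, 200)
        agent = AgentSpec(
            adapt=AdaptParams(alpha=0.5),
            noise=NoiseParams(sigma_timekeeper=5.0, seed=6),
            base_period_ms=500.0,
        )
        rec = simulate_unidirectional(stimulus, agent, first_onset=-30.0)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = fit_params_gridsearch(
                rec, agent, [0.5, 2.6], [0.0], n_sims=3, seed=0
            )
        table = res.table.set_index("alpha")
        assert math.isinf(table.loc[2.6, "loss"])
        assert res.alpha == 0.5

    def test_empty_grid_rejected(self):
        stimulus = gen_isochronous(500, 50)
        agent = AgentSpec(adapt=AdaptParams(alpha=0.5), base_period_ms=500.0)
        rec = simulate_unidirectional(stimulus, agent)
        with pytest.raises(ValidationError):
            fit_params_gridsearch(rec, agent, [], [0.0])


class TestPhaseCorrectionResponse:
    def test_pcr_equals_alpha_for_noise_free_agent(self):
        agent = AgentSpec(adapt=AdaptParams(alpha=0.5), base_period_ms=500.0)
        rec = run_perturbation_trial(500, 20, 10, 30.0, agent)
        assert estimate_pcr([rec]) == pytest.approx(0.5, abs=1e-12)

    def test_zero_gain_gives_zero_pcr(self):
        agent = AgentSpec(adapt=AdaptParams(alpha=0.0), base_period_ms=500.0)
        rec = run_perturbation_trial(500, 20, 10, 30.0, agent)
        assert estimate_pcr([rec]) == pytest.approx(0.0, abs=1e-12)

    def test_noisy_trials_average_toward_alpha(self):
        recs = [
            run_perturbation_trial(
                500, 60, 30, 30.0,
                AgentSpec(
                    adapt=AdaptParams(alpha=0.5),
                    noise=NoiseParams(sigma_timekeeper=2.0, sigma_motor=2.0, seed=100 + t),
                    base_period_ms=500.0,
                ),
            )
            for t in range(100)
        ]
        assert estimate_pcr(recs) == pytest.approx(0.5, abs=0.05)

    def test_missing_marker_rejected(self):
        agent = AgentSpec(adapt=AdaptParams(alpha=0.5), base_period_ms=500.0)
        rec = simulate_unidirectional(gen_isochronous(500, 20), agent)
        with pytest.raises(ValidationError):
            estimate_pcr([rec])
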