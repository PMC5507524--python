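"""Estimation tests: CV weighting, WNLS recovery, Fisher-information
precision, weighted residuals, and identifiability diagnostics."""

import dataclasses

import numpy as np
import pytest
from statsmodels.sandbox.stats.runs import runstest_1samp

from il6kin.estimate import (
    ObservationSeries,
    fisher_information,
    weighted_residuals,
    weights_for,
    wnls_fit,
)
from il6kin.model import ExerciseProtocol, ModelParameters, steady_state_ra
from il6kin.presets import PROTOCOLS
from il6kin.synth import DEFAULT_SCHEDULES, SamplingSchedule, generate_series


def make_series(times, values, protocol=None, cv=0.069):
    if protocol is None:
        protocol = PROTOCOLS["d1_ostrowski"]
    return ObservationSeries(times, values, protocol, cv)


class TestObservationSeries:
    def test_nonpositive_values_rejected_with_index(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            make_series(np.array([0.0, 10.0]), np.array([1.7, 0.0]))

    def test_decreasing_times_rejected(self):
        with pytest.raises(ValueError):
            make_series(np.array([10.0, 5.0]), np.array([1.7, 1.7]))


class TestWeights:
    def test_reciprocal_error_variance(self):
        s = make_series(np.array([0.0]), np.array([1.0]), cv=0.069)
        assert weights_for(s)[0] == pytest.approx(1 / 0.069**2)
        assert weights_for(s)[0] == pytest.approx(210.04, abs=0.01)

    def test_cv_scaling_law(self):
        s = make_series(np.array([0.0, 10.0]), np.array([1.0, 2.0]))
        w = weights_for(s)
        assert w[0] == pytest.approx(4 * w[1])

    def test_unit_case(self):
        s = make_series(np.array([0.0]), np.array([1.0]), cv=1.0)
        assert weights_for(s)[0] == pytest.approx(1.0)

    def test_zero_cv_rejected(self):
        s = make_series(np.array([0.0]), np.array([1.0]), cv=0.0)
        with pytest.raises(ValueError):
            weights_for(s)


class TestWnlsFit:
    def test_noiseless_recovery_from_displaced_start(self, d1_protocol, stage1_params):
        sched = DEFAULT_SCHEDULES["d1_ostrowski"]
        series = generate_series(d1_protocol, stage1_params, sched, assay_cv=0.0)
        series = dataclasses.replace(series, assay_cv=0.069)
        init = ModelParameters(
            SR_ex=2 * stage1_params.SR_ex,
            k_m=2 * stage1_params.k_m,
            k_e=2 * stage1_params.k_e,
        )
        fit = wnls_fit(series, init=init)
        assert fit.converged
        assert fit.params.free_values == pytest.approx(
            stage1_params.free_values, rel=1e-4
        )
        assert fit.wrss < 1e-8

    def test_production_rate_satisfies_steady_state_exactly(
        self, d1_protocol, stage1_params
    ):
        series = generate_series(
            d1_protocol, stage1_params, DEFAULT_SCHEDULES["d1_ostrowski"], seed=3
        )
        fit = wnls_fit(series)
        assert fit.Ra_IL6 == steady_state_ra(
            fit.params.k_e, d1_protocol.IL6_b, fit.params.V
        )

    def test_flat_series_reported_non_identifiable(self):
        # with no exercise the muscle pathway never turns on and the plasma
        # prediction is pinned at the baseline for any parameter values
        proto = ExerciseProtocol("flat", 0.0, 60.0, 0.0, 1.7)
        rng = np.random.default_rng(0)
        times = np.arange(0.0, 301.0, 30.0)
        values = 1.7 * (1 + 0.069 * rng.standard_normal(times.size))
        series = ObservationSeries(times, values, proto, 0.069)
        with pytest.warns(RuntimeWarning, match="non-identifiable"):
            fit = wnls_fit(series)
        assert not fit.precision.is_identifiable
        assert not np.isfinite(fit.cv_percent[0])  # SR_ex undetermined
        assert not np.isfinite(fit.cv_percent[1])  # k_m undetermined

    def test_too_few_observations_rejected(self, d1_protocol):
        series = make_series(
            np.array([0.0, 30.0, 60.0]), np.array([1.7, 2.0, 2.5]), d1_protocol
        )
        with pytest.raises(ValueError):
            wnls_fit(series)

    def test_log_and_natural_space_minimisers_agree(
        self, d1_protocol, stage1_params
    ):
        # the internal log transform guarantees positivity but must not move
        # the optimum on well-conditioned data
        from scipy.optimize import least_squares

        from il6kin.simulate import predict_at

        series = generate_series(
            d1_protocol, stage1_params, DEFAULT_SCHEDULES["d1_ostrowski"], seed=7
        )
        fit = wnls_fit(series)
        sqrt_w = np.sqrt(weights_for(series))

        def nat_residuals(p):
            params = ModelParameters(SR_ex=p[0], k_m=p[1], k_e=p[2])
            return sqrt_w * (
                series.il6_values - predict_at(series.protocol, params, series.times)
            )

        nat = least_squares(
            nat_residuals,
            np.array([0.05, 0.005, 0.05]),
            method="lm",
            ftol=1e-12,
            xtol=1e-12,
            gtol=1e-12,
        )
        assert fit.params.free_values == pytest.approx(nat.x, rel=1e-3)

    def test_estimator_consistency_as_noise_vanishes(
        self, d1_protocol, stage1_params
    ):
        # shrinking the noise CV must shrink the estimation error
        sched = DEFAULT_SCHEDULES["d1_ostrowski"]
        truth = stage1_params.free_values

        def mean_abs_rel_err(cv):
            errs = []
            for seed in range(8):
                s = generate_series(d1_protocol, stage1_params, sched, cv, seed=seed)
                est = wnls_fit(s).params.free_values
                errs.append(np.abs(est - truth) / truth)
            return np.mean(errs)

        assert mean_abs_rel_err(0.005) < 0.2 * mean_abs_rel_err(0.069)


class TestFisherPrecision:
    def test_matches_closed_form_for_linear_model(self):
        # y = a*t with diagonal weights: SD(a) = 1/sqrt(sum w t^2)
        t = np.array([1.0, 2.0, 4.0, 8.0])
        w = 1.0 / (0.069 * 2.0 * t) ** 2
        cov = np.linalg.inv(fisher_information(t[:, None], w))
        assert np.sqrt(cov[0, 0]) == pytest.approx(1.0 / np.sqrt(np.sum(w * t**2)))

    def test_weight_scaling_equivariance(self):
        t = np.array([1.0, 2.0, 3.0])
        J = np.column_stack([t, t**2])
        w = np.array([1.0, 2.0, 3.0])
        sd = np.sqrt(np.diag(np.linalg.inv(fisher_information(J, w))))
        sd_scaled = np.sqrt(np.diag(np.linalg.inv(fisher_information(J, 4.0 * w))))
        assert sd_scaled == pytest.approx(sd / 2.0)

    def test_fim_sd_tracks_monte_carlo_sd(self, reference_recovery):
        # the linearised precision should agree with the sampling spread of
        # the estimates to within ~30% under the reference conditions
        r = reference_recovery.replicates
        for name in ("SR_ex", "k_m", "k_e"):
            empirical = r[name].std(ddof=1)
            fim = (r[name] * r[f"{name}_cv_percent"] / 100.0).mean()
            assert 0.7 < empirical / fim < 1.3


class TestWeightedResiduals:
    def test_zero_for_perfect_fit(self, d1_protocol, stage1_params, noiseless_suite):
        series = noiseless_suite[0]
        fit = wnls_fit(series)
        r = weighted_residuals(fit, series)
        assert np.max(np.abs(r)) < 1e-4

    def test_randomly_distributed_on_matched_noise(self, d1_protocol, stage1_params):
        # when the fitted model is the generating model, the weighted
        # residuals carry no serial structure: a runs test at alpha=0.05
        # should pass in >= 90% of seeds
        sched = DEFAULT_SCHEDULES["d1_ostrowski"]
        passed = 0
        n_seeds = 50
        for seed in range(n_seeds):
            s = generate_series(d1_protocol, stage1_params, sched, seed=seed)
            fit = wnls_fit(s)
            _, p = runstest_1samp(weighted_residuals(fit, s), cutoff=0, correction=False)
            passed += p > 0.05
        assert passed >= 0.9 * n_seeds

    def test_unit_variance_under_matched_noise_model(self, reference_recovery):
        # the generator's noise is exactly the estimator's weighting model,
        # so the mean weighted residual variance sits near 1
        wrss_per_obs = reference_recovery.replicates["wrss"] / 17.0
        assert 0.5 < wrss_per_obs.mean() < 1.5
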