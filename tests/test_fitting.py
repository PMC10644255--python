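"""Global regression, offset-Weibull efflux fitting and AIC/BIC selection."""

import numpy as np
import pytest

from sterolflux import (
    CONTROL_PARAMS,
    DISEASE_PARAMS,
    DegenerateFitError,
    NoiseSpec,
    NonIdentifiableError,
    ParameterError,
    WeibullTruth,
    compare_models,
    fit_weibull_efflux,
    generate_efflux,
    generate_pulse_chase,
    global_fit,
    information_criteria,
)

DISEASE_TRUTH = {"k1": 0.03216, "k2": 0.4331, "k3": 0.1744, "k4": 0.0084, "km4": 0.0039}
CONTROL_TRUTH = {"k1": 0.01204, "k2": 0.2465, "k3": 0.09351}


class TestInformationCriteria:
    def test_parsimony_ordering_at_equal_fit(self):
        aic1, bic1 = information_criteria(0.01, 30, 3)
        aic2, bic2 = information_criteria(0.01, 30, 5)
        assert aic1 < aic2
        assert bic1 < bic2

    def test_gaussian_form_scalar_value(self):
        aic, _ = information_criteria(0.01, 30, 3)
        assert aic == pytest.approx(-234.191029, abs=1e-5)

    @pytest.mark.parametrize("n", [8, 20, 100])
    def test_bic_penalty_dominates_for_moderate_n(self, n):
        aic, bic = information_criteria(0.5, n, 4)
        assert bic - aic >= 0  # ln n >= 2 from n = 8 on

    def test_perfect_interpolation_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            information_criteria(0.0, 30, 3)

    def test_underdetermined_counts_rejected(self):
        with pytest.raises(ParameterError):
            information_criteria(0.1, 3, 3)


class TestWeibullFit:
    def test_noise_free_recovery_is_exact(self):
        truth = WeibullTruth(tau_h=135.14, mu=2.577, f0=0.4, f_inf=0.05)
        ds = generate_efflux(truth, grid_h=np.array([0.0, 12, 24, 48, 72, 96]))
        series = ds.series["intracellular_fraction"]
        fit = fit_weibull_efflux((series.time / 60.0, series.value))
        assert fit.tau == pytest.approx(135.14, rel=1e-6)
        assert fit.mu == pytest.approx(2.577, rel=1e-6)
        assert fit.f0 == pytest.approx(0.4, rel=1e-6)
        assert fit.f_inf == pytest.approx(0.05, rel=1e-4)

    def test_fixed_mu_exponential_special_case(self):
        t = np.linspace(0.0, 300.0, 12)
        tau = 80.0
        y = 0.5 * np.exp(-t / tau)
        fit = fit_weibull_efflux((t, y), fix_mu=1.0)
        assert fit.mu == 1.0
        assert fit.tau == pytest.approx(tau, rel=1e-6)

    def test_time_rescaling_rescales_tau_only(self):
        truth = WeibullTruth(tau_h=100.0, mu=1.8, f0=0.45, f_inf=0.04)
        t = np.array([0.0, 10, 25, 50, 80, 120, 160.0])
        y = truth.f_inf + (truth.f0 - truth.f_inf) * np.exp(-((t / 100.0) ** 1.8))
        for c in (1.0, 60.0, 0.5):
            fit = fit_weibull_efflux((c * t, y))
            assert fit.tau == pytest.approx(c * 100.0, rel=1e-6)
            assert fit.mu == pytest.approx(1.8, rel=1e-6)

    def test_flat_series_not_identifiable(self):
        with pytest.raises(NonIdentifiableError):
            fit_weibull_efflux((np.arange(6.0), np.full(6, 0.3)))

    def test_too_few_points_rejected(self):
        with pytest.raises(ParameterError, match=">= 5"):
            fit_weibull_efflux((np.arange(4.0), np.array([0.4, 0.3, 0.2, 0.1])))

    def test_out_of_range_fractions_rejected(self):
        with pytest.raises(ParameterError, match="\\[0, 1\\]"):
            fit_weibull_efflux((np.arange(5.0), np.array([1.4, 0.3, 0.2, 0.1, 0.05])))

    def test_monte_carlo_tau_recovery_under_noise(self):
        """200 noisy replicates on the experimental efflux grid: the median
        recovered residence time stays within 5% of the truth."""
        grid = np.array([0.0, 12, 24, 48, 72, 96])
        taus = []
        for i in range(200):
            ds = generate_efflux(
                WeibullTruth(tau_h=135.14, mu=2.577, f0=0.4, f_inf=0.05),
                grid_h=grid,
                noise=NoiseSpec(sigma=0.01 * 0.4, seed=9000 + i),
            )
            series = ds.series["intracellular_fraction"]
            try:
                fit = fit_weibull_efflux((series.time / 60.0, series.value))
            except NonIdentifiableError:
                continue
            taus.append(fit.tau)
        assert len(taus) > 150
        assert np.median(taus) == pytest.approx(135.14, rel=0.05)


class TestGlobalFit:
    def test_disease_rates_recovered_from_noise_free_pulse_chase(self, pulse_grid):
        ds = generate_pulse_chase(DISEASE_PARAMS, grid=pulse_grid)
        res = global_fit(ds, "closed_four", n_starts=3, seed=1)
        assert res.converged
        for name, value in DISEASE_TRUTH.items():
            assert res.estimates[name] == pytest.approx(value, rel=1e-3)
        assert res.rss < 1e-12

    def test_control_rates_recovered_with_three_compartment_model(self, pulse_grid):
        ds = generate_pulse_chase(CONTROL_PARAMS, variant="closed_three", grid=pulse_grid)
        res = global_fit(ds, "closed_three", n_starts=3, seed=2)
        for name, value in CONTROL_TRUTH.items():
            assert res.estimates[name] == pytest.approx(value, rel=1e-3)

    def test_refit_from_optimum_reproduces_it(self, pulse_grid):
        ds = generate_pulse_chase(
            DISEASE_PARAMS, grid=pulse_grid, noise=NoiseSpec(sigma=0.02, seed=3)
        )
        first = global_fit(ds, "closed_four", n_starts=2, seed=4)
        second = global_fit(
            ds, "closed_four", n_starts=1, initial_guess=first.estimates
        )
        assert second.rss <= first.rss * (1 + 1e-9)
        for name in first.estimates:
            assert second.estimates[name] == pytest.approx(
                first.estimates[name], rel=1e-4
            )

    def test_sd_weighting_changes_objective(self, pulse_grid):
        from sterolflux import TimeCourseDataset, TimeSeries

        ds = generate_pulse_chase(
            DISEASE_PARAMS, grid=pulse_grid, noise=NoiseSpec(sigma=0.02, seed=11)
        )
        weighted = TimeCourseDataset(
            cell_line=ds.cell_line,
            experiment=ds.experiment,
            series={
                name: TimeSeries(s.time, s.value, sd=np.full(len(s), 0.5))
                for name, s in ds.series.items()
            },
        )
        res_u = global_fit(ds, "closed_four", n_starts=1, seed=0)
        res_w = global_fit(weighted, "closed_four", n_starts=1, seed=0)
        # 1/sd^2 weighting with sd = 0.5 scales the objective by 4
        assert res_w.rss == pytest.approx(res_u.rss / 0.25, rel=1e-2)

    def test_single_phase_data_flags_four_pool_fit_as_non_identifiable(self, pulse_grid):
        ds = generate_pulse_chase(
            CONTROL_PARAMS, variant="closed_three", grid=pulse_grid,
            noise=NoiseSpec(sigma=0.02, seed=7),
        )
        res = global_fit(ds, "closed_four", n_starts=2, seed=0)
        assert any("non-identifiable" in w for w in res.warnings)

    def test_cv_is_sd_over_estimate(self, pulse_grid):
        ds = generate_pulse_chase(
            DISEASE_PARAMS, grid=pulse_grid, noise=NoiseSpec(sigma=0.02, seed=5)
        )
        res = global_fit(ds, "closed_four", n_starts=1, seed=0)
        for name in res.estimates:
            assert res.cv[name] == pytest.approx(
                res.sd[name] / res.estimates[name], rel=1e-12
            )

    def test_free_parameter_must_belong_to_variant(self, pulse_grid):
        ds = generate_pulse_chase(CONTROL_PARAMS, variant="closed_three", grid=pulse_grid)
        with pytest.raises(ParameterError, match="k6"):
            global_fit(ds, "closed_three", free_params=["k1", "k6"])

    def test_monte_carlo_recovery_bias_and_cv(self, dense_pulse_grid):
        """100 replicates at 2% additive noise on a dense-early design:
        every disease-cell rate is recovered with <5% bias and CV <= 0.4,
        comparable to the precision reported for the experimental fits."""
        truth = np.array(list(DISEASE_TRUTH.values()))
        estimates = []
        for i in range(100):
            ds = generate_pulse_chase(
                DISEASE_PARAMS,
                grid=dense_pulse_grid,
                noise=NoiseSpec(sigma=0.02, seed=500 + i),
            )
            res = global_fit(ds, "closed_four", n_starts=2, seed=i)
            estimates.append([res.estimates[k] for k in DISEASE_TRUTH])
        estimates = np.array(estimates)
        bias = estimates.mean(axis=0) / truth - 1.0
        cv = estimates.std(axis=0) / truth
        assert np.max(np.abs(bias)) < 0.05
        assert np.max(cv) <= 0.4


class TestCompareModels:
    def test_biphasic_data_selects_four_pool_model(self, pulse_grid):
        ds = generate_pulse_chase(
            DISEASE_PARAMS, grid=pulse_grid, noise=NoiseSpec(sigma=0.02, seed=21)
        )
        table, results = compare_models(
            ds, ["closed_three", "closed_four"], n_starts=2, seed=0
        )
        assert table.iloc[0]["variant"] == "closed_four"
        assert results["closed_four"].bic < results["closed_three"].bic

    def test_single_phase_data_selects_parsimonious_model(self, pulse_grid):
        ds = generate_pulse_chase(
            CONTROL_PARAMS, variant="closed_three", grid=pulse_grid,
            noise=NoiseSpec(sigma=0.02, seed=22),
        )
        table, _ = compare_models(
            ds, ["closed_three", "closed_four"], n_starts=2, seed=0
        )
        assert table.iloc[0]["variant"] == "closed_three"

    def test_single_variant_table_has_zero_deltas(self, pulse_grid):
        ds = generate_pulse_chase(
            DISEASE_PARAMS, grid=pulse_grid, noise=NoiseSpec(sigma=0.02, seed=23)
        )
        table, _ = compare_models(ds, ["closed_four"], n_starts=1, seed=0)
        assert len(table) == 1
        assert table.iloc[0]["delta_bic"] == 0.0
        assert table.iloc[0]["delta_aic"] == 0.0
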