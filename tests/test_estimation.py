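"""Estimation tests: residual arithmetic, prior penalties, the clamp-derived
insulin-sensitivity prior, optimizer contracts and reproducibility metrics."""

import numpy as np
import pytest

from mealloop.cohort import PopulationSpec, simulate_observations
from mealloop.estimation import (
    DegenerateClampError,
    FitConfig,
    FitResult,
    InvalidPriorError,
    ObservationSeries,
    PriorSpec,
    cohort_cv_summary,
    fit,
    multistart_fit,
    pooled_residual_sd,
    prior_residuals,
    reproducibility_cv,
    residual_diagnostics,
    si_prior_from_clamp,
    weighted_residuals,
)
from mealloop.model import SimulationResult, simulate


def series(protocol, times, glucose, insulin, g_sd=0.14, i_sd=5.0):
    times = np.asarray(times, float)
    return ObservationSeries(
        times=times, glucose=np.asarray(glucose, float),
        glucose_sd=np.full(times.size, g_sd),
        insulin=np.asarray(insulin, float),
        insulin_sd=np.full(times.size, i_sd), protocol=protocol)


def dummy_result(residuals, n_glucose, patient):
    residuals = np.asarray(residuals, float)
    return FitResult(params=patient, success=True, status=1, message="",
                     nfev=0, residuals=residuals,
                     prior_resid=np.empty(0), ssr_data=float(residuals @ residuals),
                     ssr_prior=0.0, ssr_total=float(residuals @ residuals),
                     diagnostics={}, glucose_mtt=117.0, insulin_mtt=112.0,
                     n_glucose=n_glucose,
                     n_insulin=residuals.size - n_glucose,
                     start_params=patient)


class TestWeightedResiduals:
    def test_perfect_model_zero_residuals(self, patient, protocol, consts):
        grid = np.arange(-20.0, 301.0, 5.0)
        sim = simulate(patient, protocol, consts, grid, method="fixed")
        idx = np.arange(0, grid.size, 6)
        obs = series(protocol, grid[idx], sim.glucose[idx], sim.insulin[idx])
        np.testing.assert_allclose(weighted_residuals(sim, obs), 0.0,
                                   atol=1e-12)

    def test_weighted_residual_arithmetic(self, patient, protocol, consts):
        # model 7.28 vs observed 7.00 with SD 0.14 -> residual exactly 2
        grid = np.arange(-20.0, 301.0, 5.0)
        sim = simulate(patient, protocol, consts, grid, method="fixed")
        idx = np.arange(0, grid.size, 6)
        obs = series(protocol, grid[idx], sim.glucose[idx] - 0.28,
                     sim.insulin[idx])
        r = weighted_residuals(sim, obs)
        np.testing.assert_allclose(r[:idx.size], 2.0, atol=1e-9)

    def test_block_ordering_glucose_then_insulin(self, patient, protocol,
                                                 consts):
        grid = np.arange(-20.0, 301.0, 5.0)
        sim = simulate(patient, protocol, consts, grid, method="fixed")
        idx = np.arange(0, grid.size, 6)
        obs = series(protocol, grid[idx], sim.glucose[idx] - 0.14,
                     sim.insulin[idx] + 5.0)
        r = weighted_residuals(sim, obs)
        np.testing.assert_allclose(r[:idx.size], 1.0, atol=1e-9)
        np.testing.assert_allclose(r[idx.size:], -1.0, atol=1e-9)

    def test_coverage_error(self, patient, protocol, consts, noise_free_obs):
        sim = simulate(patient, protocol, consts,
                       np.arange(0.0, 100.0, 5.0), method="fixed")
        with pytest.raises(Exception, match="cover"):
            weighted_residuals(sim, noise_free_obs)


class TestPriorResiduals:
    def test_at_prior_mean_zero(self, patient):
        priors = PriorSpec(means={"S_I": patient.S_I}, weights={"S_I": 10.0})
        assert prior_residuals(patient, priors) == pytest.approx([0.0])

    def test_relative_distance_arithmetic(self, patient):
        priors = PriorSpec(means={"S_I": 0.78}, weights={"S_I": 5.0})
        theta = patient.replace(S_I=0.78 * 1.1)
        assert prior_residuals(theta, priors) == pytest.approx([0.5])

    def test_no_priors_empty(self, patient):
        assert prior_residuals(patient, PriorSpec.none()).size == 0

    def test_invalid_prior_rejected(self):
        with pytest.raises(InvalidPriorError):
            PriorSpec(means={"S_I": -1.0}, weights={"S_I": 2.0})
        with pytest.raises(InvalidPriorError):
            PriorSpec(means={"bogus": 1.0}, weights={"bogus": 1.0})


class TestClampPrior:
    def test_arithmetic_from_printed_clamp_values(self):
        # M = 1655 umol/min/m2, BSA 1.91 m2, G 5 mmol/l, dI 800 pmol/l
        assert si_prior_from_clamp(1655.0, 1.91, 5.0, 890.9, 90.9) == \
            pytest.approx(1655 * 1.91 / (5 * 800), rel=1e-9)
        assert si_prior_from_clamp(1655.0, 1.91, 5.0, 890.9, 90.9) == \
            pytest.approx(0.790, abs=5e-4)

    def test_doubling_excursion_halves_prior(self):
        a = si_prior_from_clamp(1000.0, 1.8, 5.0, 500.0, 100.0)
        b = si_prior_from_clamp(1000.0, 1.8, 5.0, 900.0, 100.0)
        assert a / b == pytest.approx(2.0)

    def test_degenerate_clamp_rejected(self):
        with pytest.raises(DegenerateClampError):
            si_prior_from_clamp(1000.0, 1.8, 5.0, 90.0, 100.0)

    def test_clamp_loop_recovers_true_si(self, si_prior, patient):
        """Simulated clamp followed by the prior formula lands within 15% of
        the patient's true insulin sensitivity."""
        assert si_prior == pytest.approx(patient.S_I, rel=0.15)


class TestFit:
    def test_fixed_point_on_noise_free_data(self, patient, noise_free_obs,
                                            consts):
        res = fit(noise_free_obs, PriorSpec.none(),
                  FitConfig(n_starts=1, max_nfev=200), patient, consts)
        assert res.ssr_total < 1e-8
        free = [n for n in ("mtt_ins", "V_I", "CL_I", "S_I", "S_G", "V_G",
                            "G_b", "phi", "k_fast", "k_slow", "t_lag")]
        for name in free:
            assert getattr(res.params, name) == pytest.approx(
                getattr(patient, name), rel=1e-4)

    def test_monotone_improvement(self, patient, noise_free_obs, consts):
        start = patient.replace(S_I=patient.S_I * 1.3,
                                k_slow=patient.k_slow * 0.8)
        res = fit(noise_free_obs, PriorSpec.none(),
                  FitConfig(n_starts=1, max_nfev=60), start, consts)
        r0 = fit(noise_free_obs, PriorSpec.none(),
                 FitConfig(n_starts=1, max_nfev=1), start, consts)
        assert res.ssr_total <= r0.ssr_total + 1e-12

    def test_perturbed_start_recovers_identifiable_parameters(
            self, patient, noise_free_obs, consts):
        """From a +-30% start on noise-free data, the identifiable
        physiological quantities return to truth within 1%."""
        from mealloop.model import PARAM_NAMES
        rng = np.random.default_rng(5)
        factors = 1.0 + 0.3 * np.sign(rng.standard_normal(16))
        start_vals = {}
        for name, f in zip(PARAM_NAMES, factors):
            v = getattr(patient, name)
            start_vals[name] = v * f if name not in ("phi", "X_0") else v
        start = type(patient)(**start_vals)
        res = fit(noise_free_obs, PriorSpec.none(),
                  FitConfig(n_starts=1, max_nfev=800), start, consts)
        assert res.ssr_data < 1e-4
        assert res.params.S_I == pytest.approx(patient.S_I, rel=0.01)
        assert res.insulin_mtt == pytest.approx(112.0, rel=0.01)
        assert res.glucose_mtt == pytest.approx(117.0, rel=0.01)

    def test_objective_decomposition(self, patient, noise_free_obs, consts,
                                     si_prior):
        priors = PriorSpec.for_study(noise_free_obs, si_prior=si_prior)
        res = fit(noise_free_obs, priors, FitConfig(n_starts=1, max_nfev=50),
                  patient, consts)
        assert res.ssr_data >= 0 and res.ssr_prior >= 0
        assert res.ssr_total == pytest.approx(res.ssr_data + res.ssr_prior)


class TestMultistart:
    def test_single_start_equals_center_fit(self, patient, noise_free_obs,
                                            consts):
        cfg = FitConfig(n_starts=1, seed=3, max_nfev=40)
        ms = multistart_fit(noise_free_obs, PriorSpec.none(), cfg, consts)
        direct = fit(noise_free_obs, PriorSpec.none(), cfg,
                     ms.start_params, consts)
        np.testing.assert_array_equal(ms.params.to_array(),
                                      direct.params.to_array())

    def test_seeded_determinism(self, patient, protocol, consts, si_prior):
        spec = PopulationSpec(mean=patient)
        obs = simulate_observations(patient, protocol, spec,
                                    np.random.default_rng(7), consts)
        priors = PriorSpec.for_study(obs, si_prior=si_prior)
        cfg = FitConfig(n_starts=6, n_refine=3, seed=11, max_nfev=40)
        a = multistart_fit(obs, priors, cfg, consts)
        b = multistart_fit(obs, priors, cfg, consts)
        np.testing.assert_array_equal(a.params.to_array(),
                                      b.params.to_array())
        assert a.ssr_total == b.ssr_total

    def test_nested_search_monotonicity(self, patient, protocol, consts,
                                        si_prior):
        """More starts can only improve (or match) the best objective: the
        scrambled low-discrepancy start sequence is prefix-stable."""
        spec = PopulationSpec(mean=patient)
        obs = simulate_observations(patient, protocol, spec,
                                    np.random.default_rng(13), consts)
        priors = PriorSpec.for_study(obs, si_prior=si_prior)
        small = multistart_fit(obs, priors,
                               FitConfig(n_starts=5, n_refine=5, seed=2,
                                         max_nfev=60), consts)
        large = multistart_fit(obs, priors,
                               FitConfig(n_starts=20, n_refine=20, seed=2,
                                         max_nfev=60), consts)
        assert large.ssr_total <= small.ssr_total + 1e-9
        assert small.ssr_total <= min(e["ssr_initial"]
                                      for e in small.start_log)

    def test_prior_pull_monotone(self, patient, protocol, consts):
        """A heavier S_I prior weight pulls the estimate closer to the prior
        mean on fixed data."""
        spec = PopulationSpec(mean=patient)
        obs = simulate_observations(patient, protocol, spec,
                                    np.random.default_rng(23), consts)
        mu = 0.60  # deliberately off-truth prior
        gaps = []
        for w in (0.5, 5.0, 50.0):
            priors = PriorSpec(means={"S_I": mu}, weights={"S_I": w})
            res = fit(obs, priors, FitConfig(n_starts=1, max_nfev=120),
                      patient, consts)
            gaps.append(abs(res.params.S_I - mu))
        assert gaps[0] >= gaps[1] >= gaps[2]


class TestResidualDiagnostics:
    def test_zero_residuals(self, patient):
        d = residual_diagnostics(dummy_result(np.zeros(10), 5, patient))
        assert d["pooled"] == {"mean": 0.0, "sd": 0.0}

    def test_population_sd_convention(self, patient):
        d = residual_diagnostics(dummy_result([-1.0, 1.0, -1.0, 1.0], 2,
                                              patient))
        assert d["pooled"]["mean"] == pytest.approx(0.0)
        assert d["pooled"]["sd"] == pytest.approx(1.0)

    def test_misfit_warnings(self, patient):
        d = residual_diagnostics(dummy_result([3.0] * 12, 6, patient))
        assert any("mean" in w for w in d["warnings"])


class TestReproducibility:
    def test_identical_fits_zero_cv(self, patient, noise_free_obs, consts):
        res = fit(noise_free_obs, PriorSpec.none(),
                  FitConfig(n_starts=1, max_nfev=5), patient, consts)
        cv = reproducibility_cv(res, res)
        assert all(v == 0.0 for v in cv.values())

    def test_two_point_cv_arithmetic(self, patient):
        a = dummy_result([0.0], 1, patient.replace(S_I=1.0))
        b = dummy_result([0.0], 1, patient.replace(S_I=1.34))
        cv = reproducibility_cv(
            FitResult(**{**a.__dict__, "params": patient.replace(mtt_ins=100.0)}),
            FitResult(**{**b.__dict__, "params": patient.replace(mtt_ins=134.0)}))
        # SD = 34/sqrt(2) ~ 24.04, mean 117 -> CV ~ 20.5%
        assert cv["mtt_ins"] == pytest.approx(20.5, abs=0.1)

    def test_same_order_as_reported_day_to_day(self, patient):
        a = dummy_result([0.0], 1, patient.replace(mtt_ins=117.0))
        b = dummy_result([0.0], 1, patient.replace(mtt_ins=109.0))
        cv = reproducibility_cv(a, b)
        assert cv["mtt_ins"] == pytest.approx(5.0, abs=0.1)

    def test_cohort_summary(self, patient):
        tables = [{"S_I": 10.0}, {"S_I": 20.0}]
        out = cohort_cv_summary(tables)
        assert out["S_I"] == (15.0, 5.0)


class TestPooledResidualSd:
    def test_raw_matches_population_sd(self, patient):
        r1 = dummy_result([1.0, -1.0], 1, patient)
        r2 = dummy_result([2.0, -2.0], 1, patient)
        pooled = pooled_residual_sd([r1, r2], dof_corrected=False)
        assert pooled == pytest.approx(np.std([1, -1, 2, -2]))

    def test_correction_requires_dof(self, patient):
        with pytest.raises(ValueError):
            pooled_residual_sd([])
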