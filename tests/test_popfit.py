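"""NLME engine tests: likelihood, SAEM recovery, comparison, bootstrap, pcVPC."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import integrate, stats

import treolss as t
from treolss.popfit import (
    FitStructure,
    bootstrap,
    compare_models,
    eta_shrinkage,
    fit_population,
    marginal_minus2ll,
    pcvpc,
)


class TestMarginalLikelihood:
    def test_no_random_effects_closed_form(self, pop):
        fixed = t.PopulationModel(theta=pop.theta, prop_error_b=0.188)
        ds = t.simulate_group(fixed, 12.0, 2.0, 6, seed=3)
        m = marginal_minus2ll(fixed, ds)
        expect = 0.0
        for s in ds.subjects:
            f = t.concentration(s.true_params, s.regimen.total_dose, s.regimen.t_inf,
                                np.array([r.time for r in s.observed()]))
            y = np.array([r.conc for r in s.observed()])
            sd2 = (0.188 * f) ** 2
            expect += np.sum((y - f) ** 2 / sd2 + np.log(2 * np.pi * sd2))
        assert m.value == pytest.approx(expect, abs=1e-8)

    def test_one_dimensional_quadrature_oracle(self, pop):
        pop1 = t.PopulationModel(theta=pop.theta, omega_cl=0.3, prop_error_b=0.15)
        ds = t.simulate_group(pop1, 12.0, 2.0, 1, seed=5)
        s = ds.subjects[0]
        s.records = s.records[:1]
        m = marginal_minus2ll(pop1, t.Dataset([s]), n_samples=4000, seed=0)
        r = s.records[0]

        def integrand(eta):
            p = t.individual_parameters(pop1, s.bodyweight, t.RandomEffects(eta_cl=eta))
            f = t.concentration(p, s.regimen.total_dose, s.regimen.t_inf, r.time)
            sd2 = (0.15 * f) ** 2
            like = np.exp(-0.5 * ((r.conc - f) ** 2 / sd2 + np.log(2 * np.pi * sd2)))
            return like * stats.norm.pdf(eta, 0, 0.3)

        val, _ = integrate.quad(integrand, -4, 4)
        assert m.value == pytest.approx(-2 * np.log(val), abs=3 * max(m.mc_se, 1e-6))

    def test_stable_under_doubling_sample_count(self, pop):
        ds = t.simulate_group(pop, 12.0, 2.0, 10, seed=8)
        a = marginal_minus2ll(pop, ds, n_samples=400, seed=1)
        b = marginal_minus2ll(pop, ds, n_samples=800, seed=2)
        assert a.value == pytest.approx(b.value, abs=3 * (a.mc_se + b.mc_se))


class TestFitPopulation:
    def test_deterministic_data_recovers_typicals(self, deterministic_pop):
        ds = t.simulate_group(deterministic_pop, 12.0, 2.0, 12, seed=1)
        fit = fit_population(ds, k1=200, k2=100, seed=0, compute_se=False, is_samples=100)
        for name, truth in (("cl", 14.7), ("v1", 26.0), ("q", 2.25), ("v2", 9.93)):
            assert fit.params[name] == pytest.approx(truth, rel=1e-3)
        assert fit.converged

    def test_recovery_across_seeds(self, pop):
        # clearance recovered per seed; structural typicals within 10 % and
        # omega_Cl within 30 % as across-seed averages (the per-realization
        # MLE of the peripheral volume scatters by more than 10 %)
        fits = []
        for seed in range(5):
            ds = t.simulate_group(pop, 12.0, 2.0, 100, seed=100 + seed)
            fit = fit_population(ds, k1=250, k2=100, seed=seed, compute_se=False,
                                 is_samples=100)
            assert fit.params["cl"] == pytest.approx(14.7, rel=0.10)
            fits.append(fit)
        for name, truth in (("cl", 14.7), ("v1", 26.0), ("v2", 9.93)):
            mean_est = np.mean([f.params[name] for f in fits])
            assert mean_est == pytest.approx(truth, rel=0.10), name
        assert np.mean([f.omegas["cl"] for f in fits]) == pytest.approx(0.255, rel=0.30)

    def test_matches_direct_marginal_maximisation(self, pop):
        # cross-check the SAEM optimum against direct optimisation of the
        # importance-sampled -2LL over (Cl, b) with the rest held fixed
        ds = t.simulate_group(pop, 12.0, 2.0, 10, seed=21)
        fit = fit_population(ds, k1=200, k2=80, seed=3, compute_se=False, is_samples=200)
        est = fit.estimates
        from scipy.optimize import minimize

        def obj(x):
            cand = replace(est, theta=replace(est.theta, cl=float(x[0])),
                           prop_error_b=float(x[1]))
            return marginal_minus2ll(cand, ds, n_samples=300, seed=11).value

        res = minimize(obj, [est.theta.cl, est.prop_error_b], method="Nelder-Mead",
                       options={"xatol": 1e-3, "fatol": 1e-3})
        assert fit.params["cl"] == pytest.approx(res.x[0], rel=0.03)
        assert fit.error["b"] == pytest.approx(res.x[1], rel=0.10)

    def test_aic_bic_identities(self, pop):
        ds = t.simulate_group(pop, 12.0, 2.0, 10, seed=2)
        fit = fit_population(ds, k1=60, k2=30, seed=0, compute_se=False, is_samples=100)
        assert fit.aic == pytest.approx(fit.minus2ll + 2 * fit.n_params)
        assert fit.bic == pytest.approx(fit.minus2ll + fit.n_params * np.log(10))


def _stub_fit(m2ll: float, p: int, structure: FitStructure) -> t.FitResult:
    return t.FitResult(
        params={}, exponents={}, omegas={}, corr={}, error={}, se=None,
        rse_percent=None, minus2ll=m2ll, minus2ll_mc_se=0.0, aic=m2ll + 2 * p,
        bic=m2ll + p * np.log(10), shrinkage={}, eta_hat=np.zeros((1, 1)),
        n_params=p, n_subjects=10, converged=True, se_ok=False, structure=structure,
    )


class TestModelComparison:
    def test_decision_thresholds(self):
        full = _stub_fit(100.0, 9, FitStructure(n_compartments=2))
        sig = compare_models(_stub_fit(112.0, 8, FitStructure(n_compartments=1)), full)
        assert sig.nested and sig.df == 1
        assert sig.significant_forward and sig.significant_backward
        mid = compare_models(_stub_fit(108.0, 8, FitStructure(n_compartments=1)), full)
        assert not mid.significant_forward and mid.significant_backward
        weak = compare_models(_stub_fit(105.0, 8, FitStructure(n_compartments=1)), full)
        assert not weak.significant_forward and not weak.significant_backward

    def test_thresholds_are_chi_square_quantiles(self):
        assert stats.chi2.ppf(0.999, 1) == pytest.approx(10.83, abs=0.01)
        assert stats.chi2.ppf(0.99, 1) == pytest.approx(6.63, abs=0.01)

    def test_non_nested_refuses_lrt(self):
        a = _stub_fit(120.0, 9, FitStructure(error_model="additive"))
        b = _stub_fit(100.0, 9, FitStructure(error_model="proportional"))
        cmp_ = compare_models(a, b)
        assert not cmp_.nested
        assert cmp_.df is None and cmp_.significant_forward is None
        assert cmp_.delta_aic == pytest.approx(20.0)


class TestShrinkage:
    def test_closed_cases(self):
        rng = np.random.default_rng(0)
        eta = rng.normal(0, 0.3, 2000)
        assert eta_shrinkage(eta, np.std(eta, ddof=1)) == pytest.approx(0.0, abs=1e-9)
        assert eta_shrinkage(np.full(50, 0.2), 0.3) == pytest.approx(100.0)

    def test_ninety_percent_sd_gives_19_percent(self):
        rng = np.random.default_rng(1)
        eta = rng.normal(0, 1, 4000)
        eta = eta / np.std(eta, ddof=1) * 0.9 * 0.5  # SD exactly 0.9 * omega
        assert eta_shrinkage(eta, 0.5) == pytest.approx(19.0, abs=1e-6)

    def test_zero_omega_rejected(self):
        with pytest.raises(ValueError):
            eta_shrinkage([0.1, 0.2, 0.3], 0.0)


class TestBootstrap:
    def test_single_replicate_ci_collapses(self, pop):
        ds = t.simulate_group(pop, 12.0, 2.0, 8, seed=6)
        res = bootstrap(ds, 1, seed=0, fit_kwargs=dict(k1=40, k2=20, is_samples=50))
        for k in res.median:
            assert res.ci5[k] == res.median[k] == res.ci95[k]

    def test_percentiles_match_sort_oracle(self, pop):
        ds = t.simulate_group(pop, 12.0, 2.0, 8, seed=6)
        res = bootstrap(ds, 5, seed=1, fit_kwargs=dict(k1=40, k2=20, is_samples=50))
        for k, v in res.samples.items():
            assert res.median[k] == pytest.approx(np.sort(v)[len(v) // 2])

    def test_coverage_of_truth_scaled_down(self, pop):
        ds = t.simulate_group(pop, 12.0, 2.0, 30, seed=9)
        res = bootstrap(ds, 20, seed=2, fit_kwargs=dict(k1=80, k2=40, is_samples=50))
        truth = {"theta_cl": 14.7, "theta_v1": 26.0, "theta_q": 2.25, "theta_v2": 9.93}
        covered = sum(res.ci5[k] <= v <= res.ci95[k] for k, v in truth.items())
        assert covered >= 3


class TestPcVpc:
    def test_self_simulated_coverage(self, pop, rich_noisy_cohort):
        summary = pcvpc(rich_noisy_cohort, pop, n_sim=400, seed=5)
        assert summary.fraction_observed_in_95band() >= 0.9

    def test_band_ordering(self, pop, rich_noisy_cohort):
        s = pcvpc(rich_noisy_cohort, pop, n_sim=200, seed=1)
        assert np.all(s.band95[:, :, 0] <= s.band50[:, :, 0] + 1e-12)
        assert np.all(s.band50[:, :, 1] <= s.band95[:, :, 1] + 1e-12)
        assert np.all(s.observed[:, 0] <= s.observed[:, 1])
        assert np.all(s.observed[:, 1] <= s.observed[:, 2])

    def test_homogeneous_cohort_equals_plain_vpc(self, pop):
        # identical weights and design: the prediction correction is exactly 1
        ds = t.simulate_group(pop, 12.0, 2.0, 40, seed=3)
        for s in ds.subjects:
            s.bodyweight = 20.0
            s.bsa = t.bsa_from_weight(20.0)
        # equalise doses so PRED is record-identical within bins
        from treolss.cohort import DoseRegimen

        for s in ds.subjects:
            s.regimen = DoseRegimen(12.0, 2.0, 12.0 * s.bsa * 1000.0)
        summary = pcvpc(ds, pop, n_sim=150, seed=2)
        raw = {}
        for s in ds.subjects:
            for r in s.observed():
                raw.setdefault(round(r.time, 6), []).append(r.conc)
        for bt, obs_row in zip(summary.bin_median_time, summary.observed):
            np.testing.assert_allclose(obs_row, np.percentile(raw[round(bt, 6)], (5, 50, 95)),
                                       rtol=1e-10)

    def test_bands_match_stored_simulation_matrix(self, pop):
        ds = t.simulate_group(pop, 12.0, 2.0, 25, seed=4)
        s = pcvpc(ds, pop, n_sim=150, seed=7, keep_simulations=True)
        assert s.sim_percentiles is not None
        for b in range(len(s.bin_median_time)):
            np.testing.assert_allclose(
                s.band95[b, :, 0], np.percentile(s.sim_percentiles[b], 2.5, axis=0))
            np.testing.assert_allclose(
                s.band50[b, :, 1], np.percentile(s.sim_percentiles[b], 75, axis=0))

    def test_requires_minimum_simulations(self, pop, rich_noisy_cohort):
        with pytest.raises(t.ConfigurationError):
            pcvpc(rich_noisy_cohort, pop, n_sim=10)


class TestWaldCovariateTest:
    def test_requires_estimated_exponents(self):
        fit = _stub_fit(100.0, 9, FitStructure())
        with pytest.raises(t.ConfigurationError):
            t.popfit.wald_covariate_test(fit, "cl")


class TestThreeCompartment:
    def test_concentration_matches_ode_oracle(self):
        from scipy.integrate import solve_ivp

        from treolss.popfit import _conc_3cmt_scalar

        cl, v1, q2, v2, q3, v3 = 12.0, 20.0, 3.0, 8.0, 1.0, 30.0
        k10, k12, k21 = cl / v1, q2 / v1, q2 / v2
        k13, k31 = q3 / v1, q3 / v3
        times = np.array([0.5, 1.0, 2.0, 3.0, 5.0, 8.0, 12.0, 24.0])

        def rhs(tt, a):
            inp = 10000 / 2.0 if tt < 2.0 else 0.0
            return [inp - (k10 + k12 + k13) * a[0] + k21 * a[1] + k31 * a[2],
                    k12 * a[0] - k21 * a[1],
                    k13 * a[0] - k31 * a[2]]

        sol = solve_ivp(rhs, (0, 24.0), [0.0, 0.0, 0.0], t_eval=times,
                        rtol=1e-10, atol=1e-12, max_step=0.5)
        ana = _conc_3cmt_scalar(cl, v1, q2, v2, q3, v3, 10000, 2.0, times)
        np.testing.assert_allclose(ana, sol.y[0] / v1, rtol=1e-7)

    def test_reduces_to_two_compartment_when_third_is_negligible(self, typical):
        from treolss.popfit import _conc_3cmt_scalar

        times = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 12.0])
        two = t.concentration(typical, 20000, 2.0, times)
        three = _conc_3cmt_scalar(typical.cl, typical.v1, typical.q, typical.v2,
                                  1e-9, 1.0, 20000, 2.0, times)
        np.testing.assert_allclose(three, two, rtol=1e-6)
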