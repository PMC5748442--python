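"""Unit and property tests of the structural PK model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad, solve_ivp

import treolss as t
from treolss.pkmodel import _profile


def _ode_concentration(p, dose, t_inf, times):
    """Independent oracle: adaptive integration of the two-compartment ODEs."""
    k10, k12, k21 = p.cl / p.v1, p.q / p.v1, p.q / p.v2

    def rhs(tt, a):
        inp = dose / t_inf if tt < t_inf else 0.0
        return [inp - (k10 + k12) * a[0] + k21 * a[1], k12 * a[0] - k21 * a[1]]

    sol = solve_ivp(rhs, (0.0, max(times) + 1e-9), [0.0, 0.0], t_eval=times,
                    rtol=1e-10, atol=1e-12, max_step=float(t_inf) / 4)
    return sol.y[0] / p.v1


class TestIndividualParameters:
    def test_reference_weight_typicals(self, pop):
        p = t.individual_parameters(pop, 70.0, t.RandomEffects())
        assert (p.cl, p.v1, p.q, p.v2) == pytest.approx((14.7, 26.0, 2.25, 9.93))

    def test_eta_acts_multiplicatively(self, pop):
        p = t.individual_parameters(pop, 70.0, t.RandomEffects(eta_cl=np.log(2)))
        assert p.cl == pytest.approx(29.4)
        assert (p.v1, p.q, p.v2) == pytest.approx((26.0, 2.25, 9.93))

    def test_allometric_halved_weight(self, pop):
        # Cl scales with (BW/70)^0.75, volumes linearly, Q not at all
        p = t.individual_parameters(pop, 35.0, t.RandomEffects())
        assert p.cl == pytest.approx(14.7 * 0.5**0.75, rel=1e-12)
        assert p.v1 == pytest.approx(13.0)
        assert p.v2 == pytest.approx(4.965)
        assert p.q == pytest.approx(2.25)

    def test_nonpositive_weight_rejected(self, pop):
        with pytest.raises(ValueError):
            t.individual_parameters(pop, 0.0, t.RandomEffects())


class TestMicroConstants:
    def test_final_model_rates(self, typical):
        mc = t.micro_constants(typical)
        assert mc.k10 == pytest.approx(0.5654, rel=1e-3)
        assert mc.k12 == pytest.approx(0.08654, rel=1e-3)
        assert mc.k21 == pytest.approx(0.2266, rel=1e-3)
        assert mc.alpha > mc.beta > 0

    def test_one_compartment_limit(self):
        mc = t.micro_constants(t.PKParameters(cl=10.0, v1=20.0, q=0.0, v2=5.0))
        assert mc.k12 == mc.k21 == 0.0
        assert mc.alpha == pytest.approx(0.5)
        assert mc.beta == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(1, 50), st.floats(1, 80), st.floats(0.01, 20), st.floats(1, 50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_vieta_identities(self, cl, v1, q, v2):
        p = t.PKParameters(cl, v1, q, v2)
        mc = t.micro_constants(p)
        assert mc.alpha * mc.beta == pytest.approx(mc.k10 * mc.k21, rel=1e-9)
        assert mc.alpha + mc.beta == pytest.approx(mc.k10 + mc.k12 + mc.k21, rel=1e-12)


class TestConcentration:
    def test_zero_before_infusion_starts(self, typical):
        assert t.concentration(typical, 22200, 2.0, 0.0) == 0.0

    def test_one_compartment_closed_form(self):
        p = t.PKParameters(cl=14.7, v1=26.0, q=0.0, v2=1.0)
        expect = (22200 / 14.7) * (1 - np.exp(-14.7 / 26.0))
        assert t.concentration(p, 22200, 1.0, 1.0) == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(652.2, abs=0.1)

    def test_matches_ode_oracle_at_6h(self, typical):
        ana = t.concentration(typical, 22200, 2.0, 6.0)
        ode = _ode_concentration(typical, 22200, 2.0, np.array([6.0]))[0]
        assert ana == pytest.approx(ode, rel=1e-6)

    def test_matches_ode_oracle_random_sweep(self):
        rng = np.random.default_rng(7)
        times = np.array([0.5, 1.0, 1.5, 2.0, 3.0, 5.0, 8.0, 12.0])
        for _ in range(20):
            p = t.PKParameters(*np.exp(rng.uniform(np.log(0.5), np.log(50), 4)))
            ana = t.concentration(p, 10000, 2.0, times)
            ode = _ode_concentration(p, 10000, 2.0, times)
            np.testing.assert_allclose(ana, ode, rtol=1e-6, atol=1e-8 * ana.max())

    def test_linearity_in_dose(self, typical):
        tt = np.linspace(0.1, 20, 40)
        np.testing.assert_allclose(
            t.concentration(typical, 2 * 11000, 1.0, tt),
            2 * t.concentration(typical, 11000, 1.0, tt),
            rtol=1e-12,
        )

    def test_continuous_at_end_of_infusion_and_decreasing_after(self, typical):
        eps = 1e-7
        left = t.concentration(typical, 22200, 2.0, 2.0 - eps)
        right = t.concentration(typical, 22200, 2.0, 2.0 + eps)
        assert left == pytest.approx(right, rel=1e-5)
        tail = t.concentration(typical, 22200, 2.0, np.linspace(2.0, 24.0, 100))
        assert np.all(np.diff(tail) < 0)

    def test_negative_time_rejected(self, typical):
        with pytest.raises(ValueError):
            t.concentration(typical, 22200, 2.0, -0.1)


class TestAucFromClearance:
    def test_basic_arithmetic(self):
        assert t.auc_from_clearance(0.0, 14.7) == 0.0
        assert t.auc_from_clearance(22200, 14.7) == pytest.approx(1510.2, abs=0.05)
        with pytest.raises(ValueError):
            t.auc_from_clearance(100.0, 0.0)

    def test_equals_integral_of_concentration(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            p = t.PKParameters(*np.exp(rng.uniform(np.log(1), np.log(40), 4)))
            integral, _ = quad(lambda x: t.concentration(p, 5000, 2.0, x), 0, np.inf, limit=400)
            assert integral == pytest.approx(t.auc_from_clearance(5000, p.cl), rel=1e-4)


class TestResidualError:
    def test_zero_draw_identity(self, pop):
        assert t.apply_residual_error(100.0, pop, 0.0) == pytest.approx(100.0)

    def test_one_sd_draw(self, pop):
        assert t.apply_residual_error(100.0, pop, 0.188) == pytest.approx(118.8)

    def test_monte_carlo_sd(self, pop):
        rng = np.random.default_rng(0)
        obs, _ = t.pkmodel.simulate_observations(np.full(100_000, 100.0), pop, rng)
        assert np.std(obs) == pytest.approx(18.8, abs=0.3)

    def test_negative_results_truncated(self, pop):
        obs = t.apply_residual_error(np.array([10.0, 10.0]), pop, np.array([-2.0, 0.5]))
        assert obs[0] == 0.0 and obs[1] == pytest.approx(15.0)


class TestRandomEffects:
    def test_degenerate_zero_omega(self):
        pop = t.PopulationModel(theta=t.PKParameters(14.7, 26.0, 2.25, 9.93))
        etas = t.sample_random_effects(pop, 10, seed=0)
        assert all(e.as_array().tolist() == [0, 0, 0] for e in etas)

    def test_sample_moments_match_configuration(self, pop):
        arr = np.array([e.as_array() for e in t.sample_random_effects(pop, 100_000, seed=1)])
        assert np.std(arr[:, 0]) == pytest.approx(0.255, abs=0.005)
        assert np.std(arr[:, 1]) == pytest.approx(0.514, abs=0.008)
        corr = np.corrcoef(arr[:, 0], arr[:, 1])[0, 1]
        assert corr == pytest.approx(0.714, abs=0.02)
        assert abs(np.corrcoef(arr[:, 0], arr[:, 2])[0, 1]) < 0.02

    def test_reproducible_under_seed(self, pop):
        a = t.sample_random_effects(pop, 5, seed=9)
        b = t.sample_random_effects(pop, 5, seed=9)
        assert a == b

    def test_invalid_correlation_rejected(self):
        with pytest.raises(t.ConfigurationError):
            t.PopulationModel(theta=t.PKParameters(1, 1, 1, 1), omega_cl=0.2,
                              omega_v1=0.2, corr_cl_v1=1.5)
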