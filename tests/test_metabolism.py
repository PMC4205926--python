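"""Core physiology: fluxes, regulation signs, fasting steady state."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from qspsim.effects import RateMultipliers
from qspsim.errors import ConfigurationError, ConvergenceError, DomainError
from qspsim.metabolism import (
    MetabolicKernel, MetabolicState, build_default_parameters,
    glucagon_dynamics, gut_absorption_flux, hepatic_glucose_fluxes,
    insulin_secretion_rate, metabolic_rhs, muscle_glucose_dynamics,
    renal_glucose_excretion, steady_state,
)
from qspsim.metabolism.state import STATE_NAMES

IDENT = RateMultipliers()


class TestMetabolicRhs:
    def test_fasting_steady_state_has_zero_derivatives(self, healthy_params,
                                                       t2dm_params):
        for params, ss in ((healthy_params, steady_state(healthy_params)),
                           (t2dm_params, steady_state(t2dm_params))):
            dy = metabolic_rhs(0.0, ss, params, IDENT)
            assert np.max(np.abs(dy)) < 1e-6

    def test_brain_uptake_glucose_independent(self, t2dm_params):
        """The brain consumes at a constant rate at 5 and at 15 mM glucose."""
        kern = MetabolicKernel(t2dm_params)
        assert kern.brain_uptake(5.0) == kern.brain_uptake(15.0)
        assert kern.brain_uptake(5.0) == t2dm_params["brain_glucose_uptake"]

    def test_lower_hgp_multiplier_lowers_glucose_derivative(self, t2dm_params,
                                                            t2dm_state):
        d1 = metabolic_rhs(0.0, t2dm_state, t2dm_params, IDENT)
        half = RateMultipliers(hepatic_glucose_production=0.5)
        d2 = metabolic_rhs(0.0, t2dm_state, t2dm_params, half)
        assert d2[0] < d1[0]

    def test_negative_state_rejected(self, t2dm_params, t2dm_state):
        t2dm_state.G_plasma = -1.0
        with pytest.raises(DomainError):
            metabolic_rhs(0.0, t2dm_state, t2dm_params, IDENT)

    def test_incomplete_effect_map_rejected(self, t2dm_params, t2dm_state):
        with pytest.raises(ConfigurationError):
            metabolic_rhs(0.0, t2dm_state, t2dm_params,
                          {"hepatic_glucose_production": 0.5})


class TestGutAbsorption:
    def test_empty_gut_zero_flux(self, healthy_params):
        flux = gut_absorption_flux(0.0, MetabolicState(), healthy_params)
        assert flux == {"carb": 0.0, "fat": 0.0, "protein": 0.0}

    def _carb_chain(self, params, delay):
        """Integrate the stomach->gut->absorbed chain for a 75 g bolus."""
        kern = MetabolicKernel(params)

        def rhs(t, y):
            st, gut, absorbed = y
            s = MetabolicState()
            s.gut_carb = max(gut, 0.0)
            f = gut_absorption_flux(t, s, params, delay)["carb"]
            return [-kern.ke_c * st, kern.ke_c * st - f, f]

        sol = solve_ivp(rhs, (0.0, 48.0), [75.0, 0.0, 0.0], rtol=1e-10,
                        atol=1e-12, dense_output=True)
        t = np.linspace(0.0, 48.0, 2000)
        return t, sol.sol(t)

    def test_bolus_mass_balance(self, healthy_params):
        """All 75 g of an oral carbohydrate bolus is eventually absorbed."""
        _, y = self._carb_chain(healthy_params, 1.0)
        assert y[2, -1] == pytest.approx(75.0, rel=1e-4)
        # conservation holds along the way, not just at the end
        assert np.allclose(y.sum(axis=0), 75.0, rtol=1e-6)

    def test_delay_shifts_peak_not_total(self, healthy_params):
        kern = MetabolicKernel(healthy_params)
        t, y1 = self._carb_chain(healthy_params, 1.0)
        _, y2 = self._carb_chain(healthy_params, 0.5)
        f1 = kern.ka_c * 1.0 * y1[1]
        f2 = kern.ka_c * 0.5 * y2[1]
        assert t[np.argmax(f2)] > t[np.argmax(f1)]
        assert y2[2, -1] == pytest.approx(y1[2, -1], rel=1e-3)

    def test_negative_delay_rejected(self, healthy_params):
        with pytest.raises(DomainError):
            gut_absorption_flux(0.0, MetabolicState(), healthy_params, 0.0)


class TestHepaticFluxes:
    def test_empty_glycogen_store_stops_glycogenolysis(self, t2dm_params,
                                                       t2dm_state):
        t2dm_state.Gly_liver = 0.0
        fl = hepatic_glucose_fluxes(t2dm_state, t2dm_params, IDENT)
        assert fl["glycogenolysis"] == 0.0

    def test_insulin_suppresses_net_hepatic_output(self, t2dm_params,
                                                   t2dm_ss):
        outputs = []
        for ie in (20.0, 60.0, 150.0, 400.0):
            s = MetabolicState.from_vector(t2dm_ss.to_vector())
            s.IE_liver = ie
            fl = hepatic_glucose_fluxes(s, t2dm_params, IDENT)
            outputs.append(fl["G6Pase"] + fl["glycogenolysis"]
                           + fl["gluconeogenesis"] - fl["glucokinase"]
                           - fl["glycogen_synthesis"])
        assert all(a > b for a, b in zip(outputs, outputs[1:]))

    def test_hgp_multiplier_scales_production_terms(self, t2dm_params,
                                                    t2dm_state):
        base = hepatic_glucose_fluxes(t2dm_state, t2dm_params, IDENT)
        scaled = hepatic_glucose_fluxes(
            t2dm_state, t2dm_params,
            RateMultipliers(hepatic_glucose_production=0.7))
        assert scaled["glycogenolysis"] == pytest.approx(0.7 * base["glycogenolysis"])
        assert scaled["gluconeogenesis"] == pytest.approx(0.7 * base["gluconeogenesis"])
        for unaffected in ("glucokinase", "G6Pase", "glycogen_synthesis"):
            assert scaled[unaffected] == pytest.approx(base[unaffected])


class TestMuscle:
    def test_no_release_pathway(self, t2dm_params, t2dm_state):
        fl = muscle_glucose_dynamics(t2dm_state, t2dm_params, IDENT)
        assert set(fl) == {"uptake", "glycogen_synthesis", "oxidation"}

    def test_zero_insulin_leaves_basal_uptake(self, healthy_params):
        s = MetabolicState()
        s.IE_muscle = 0.0
        fl = muscle_glucose_dynamics(s, healthy_params, IDENT)
        kern = MetabolicKernel(healthy_params)
        expected = kern.mu_v0 * s.G_plasma / (kern.mu_km + s.G_plasma)
        assert fl["uptake"] == pytest.approx(expected)

    def test_t2dm_uptake_below_healthy_at_matched_state(self, healthy_params,
                                                        t2dm_params,
                                                        t2dm_state):
        fl_h = muscle_glucose_dynamics(t2dm_state, healthy_params, IDENT)
        fl_d = muscle_glucose_dynamics(t2dm_state, t2dm_params, IDENT)
        assert fl_h["uptake"] > fl_d["uptake"]

    def test_glycogen_synthesis_never_exceeds_uptake(self, t2dm_params):
        rng = np.random.default_rng(7)
        for _ in range(100):
            s = MetabolicState()
            s.G_plasma = rng.uniform(3.0, 25.0)
            s.Gly_muscle = rng.uniform(0.0, 400.0)
            s.IE_muscle = rng.uniform(0.0, 900.0)
            fl = muscle_glucose_dynamics(s, t2dm_params, IDENT)
            assert fl["glycogen_synthesis"] <= fl["uptake"] + 1e-12
            assert fl["oxidation"] >= -1e-12


class TestRenalExcretion:
    def test_below_threshold_zero(self, healthy_params):
        assert renal_glucose_excretion(5.0, healthy_params) == 0.0

    def test_continuous_at_threshold(self, healthy_params):
        thr = healthy_params["renal_threshold"]
        assert renal_glucose_excretion(thr, healthy_params) == 0.0
        just_above = renal_glucose_excretion(thr + 1e-6, healthy_params)
        assert 0.0 <= just_above < 1e-6

    def test_monotone_above_threshold(self, healthy_params):
        grid = [renal_glucose_excretion(g, healthy_params)
                for g in np.linspace(8.0, 20.0, 60)]
        assert all(b >= a for a, b in zip(grid, grid[1:]))
        assert renal_glucose_excretion(15.0, healthy_params) > \
            renal_glucose_excretion(12.0, healthy_params)


class TestInsulinSecretion:
    def test_zero_function_scaler_silences_secretion(self, t2dm_params,
                                                     t2dm_state):
        t2dm_state.B_func = 0.0
        assert insulin_secretion_rate(t2dm_state, t2dm_params, IDENT) == 0.0

    def test_ca_gain_multiplier_raises_rate(self, t2dm_params, t2dm_state):
        base = insulin_secretion_rate(t2dm_state, t2dm_params, IDENT)
        amplified = insulin_secretion_rate(
            t2dm_state, t2dm_params,
            RateMultipliers(insulin_secretion_ca_gain=2.0))
        assert amplified > base

    def test_scales_with_mass_and_function(self, t2dm_params, t2dm_state):
        base = insulin_secretion_rate(t2dm_state, t2dm_params, IDENT)
        t2dm_state.B_mass *= 2.0
        assert insulin_secretion_rate(t2dm_state, t2dm_params, IDENT) == \
            pytest.approx(2.0 * base)

    def test_glucose_dependence_after_signal_equilibration(self, t2dm_params,
                                                           t2dm_state):
        kern = MetabolicKernel(t2dm_params)
        rates = []
        for g in (5.0, 15.0):
            s = MetabolicState.from_vector(t2dm_state.to_vector())
            s.G_plasma = g
            s.S_camp, s.S_ca = kern.beta_signal_targets(g, s.GLP1, s.GIP)
            rates.append(insulin_secretion_rate(s, t2dm_params, IDENT))
        assert rates[1] > rates[0]


class TestGlucagon:
    def test_hypoglycemia_stimulates_secretion(self, t2dm_params, t2dm_state):
        kern = MetabolicKernel(t2dm_params)
        low = kern.glucagon_secretion(3.0, t2dm_state.I_plasma)
        high = kern.glucagon_secretion(12.0, t2dm_state.I_plasma)
        assert low > high

    def test_exchange_conserves_mass_without_source_and_sink(self,
                                                             healthy_params):
        params = healthy_params.with_overrides({
            "glucagon_secretion_max": 0.0, "glucagon_clearance_rate": 0.0})
        s = MetabolicState()
        s.Gn_1, s.Gn_2 = 35.0, 5.0
        d1, d2 = glucagon_dynamics(s, params)
        assert d1 + d2 == pytest.approx(0.0, abs=1e-12)

    def test_fasting_equilibrium(self, t2dm_params, t2dm_ss):
        d1, d2 = glucagon_dynamics(t2dm_ss, t2dm_params)
        assert abs(d1) < 1e-6 and abs(d2) < 1e-6


class TestSteadyState:
    def test_healthy_fasting_glucose_normoglycemic(self, healthy_ss):
        assert 4.0 <= healthy_ss.G_plasma <= 6.0

    def test_t2dm_fixture_hyperglycemic_in_enrollment_band(self, t2dm_ss):
        assert 7.0 <= t2dm_ss.G_plasma <= 12.0

    def test_unique_for_different_starting_guesses(self, t2dm_params,
                                                   t2dm_ss):
        start = MetabolicState()
        start.G_plasma = 15.0
        start.I_plasma = 300.0
        start.Gly_liver = 5.0
        start.TAG_adipose = t2dm_params["tag_adipose_ref"]
        start.B_func = t2dm_params["beta_cell_function"]
        again = steady_state(t2dm_params, start=start)
        assert np.allclose(again.to_vector(), t2dm_ss.to_vector(),
                           rtol=1e-5, atol=1e-7)

    def test_reports_residual_on_failure(self, healthy_params):
        with pytest.raises(ConvergenceError) as exc:
            steady_state(healthy_params, tol=1e-300)
        assert exc.value.residual is not None
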