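"""Drug PK sub-models, PD mapping, and exposure metrics."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.integrate import solve_ivp

from qspsim.effects import EFFECT_TAGS
from qspsim.errors import ConfigurationError, DomainError
from qspsim.hill import ACTIVATION, INHIBITION
from qspsim.pkpd import (
    DrugParameters, EffectSpec, PKState, apply_dose, gallbladder_empty,
    metformin_parameters, metformin_pk_rhs, pd_effects, pk_metrics,
    pk_rhs_vector, tak875_parameters, tak875_pk_rhs,
)


def integrate_pk(dp, doses, t_end, triggers=(), n_pts=4000):
    """Dose/trigger-driven PK integration; returns (t, state-matrix)."""
    y = np.zeros(6)
    events = sorted([(t, "dose", mg) for t, mg in doses]
                    + [(t, "trigger", None) for t in triggers]) + [(t_end, "end", None)]
    ts, ys = [], []
    t = 0.0
    for te, kind, mg in events:
        if te > t:
            t_eval = np.linspace(t, te, max(2, int((te - t) / t_end * n_pts)))
            sol = solve_ivp(lambda tt, yy: pk_rhs_vector(yy, dp), (t, te), y,
                            method="LSODA", rtol=1e-10, atol=1e-12,
                            t_eval=t_eval)
            ts.append(sol.t)
            ys.append(sol.y)
            y = sol.y[:, -1].copy()
            t = te
        if kind == "dose":
            y[0] += dp.F * mg
        elif kind == "trigger":
            released = dp.gb_empty_frac * y[4]
            y[4] -= released
            y[0] += released
    return np.concatenate(ts), np.concatenate(ys, axis=1)


class TestMetforminPK:
    def test_empty_system_is_stationary(self):
        dp = metformin_parameters()
        d = metformin_pk_rhs(0.0, PKState("metformin"), dp)
        assert np.all(d == 0.0)

    def test_auc_matches_closed_form(self):
        """AUC to infinity of a single oral dose equals F*dose/CL."""
        dp = metformin_parameters()
        t, y = integrate_pk(dp, [(0.0, 500.0)], 400.0)
        conc = y[1] / dp.V_central * 1000.0  # ng/mL
        auc = np.trapezoid(conc, t)
        assert auc == pytest.approx(dp.F * 500.0 / dp.CL * 1000.0, rel=0.01)

    def test_dose_linearity(self):
        dp = metformin_parameters()
        t1, y1 = integrate_pk(dp, [(0.0, 500.0)], 96.0)
        t2, y2 = integrate_pk(dp, [(0.0, 1000.0)], 96.0)
        c1, c2 = y1[1] / dp.V_central, y2[1] / dp.V_central
        assert c2.max() == pytest.approx(2.0 * c1.max(), rel=1e-6)
        assert np.trapezoid(c2, t2) == pytest.approx(
            2.0 * np.trapezoid(c1, t1), rel=1e-6)

    def test_superposition_of_twice_daily_doses(self):
        """Linear PK: the bid profile equals the sum of lagged single doses."""
        dp = metformin_parameters()
        dose_times = [24.0 * d + off for d in range(4) for off in (9.0, 21.0)]
        t, y = integrate_pk(dp, [(td, 500.0) for td in dose_times], 120.0)
        multi = y[1] / dp.V_central
        grid = np.linspace(0.0, 120.0, 600)
        multi_g = np.interp(grid, t, multi)
        t1, y1 = integrate_pk(dp, [(0.0, 500.0)], 121.0)
        single = lambda tau: np.interp(tau, t1, y1[1] / dp.V_central,
                                       left=0.0, right=0.0)
        summed = sum(np.where(grid >= td, single(grid - td), 0.0)
                     for td in dose_times)
        assert np.allclose(multi_g, summed, rtol=5e-3, atol=1e-4)

    def test_mass_balance_every_instant(self):
        dp = metformin_parameters()
        t, y = integrate_pk(dp, [(0.0, 500.0), (12.0, 500.0)], 72.0)
        mask = np.abs(t - 12.0) > 1e-9  # the dose instant itself is ambiguous
        administered = np.where(t > 12.0, 1000.0, 500.0)[mask]
        in_system = y[:6].sum(axis=0)[mask]
        non_absorbed = administered * (1.0 - dp.F)
        assert np.allclose(in_system + non_absorbed, administered, rtol=1e-9)


class TestTak875EHRC:
    def test_zero_biliary_fraction_reduces_to_plain_oral_model(self):
        dp = tak875_parameters()
        dp0 = replace(dp, biliary_frac=0.0)
        plain = replace(dp0, model="oral_3c")
        t1, y1 = integrate_pk(dp0, [(0.0, 100.0)], 96.0)
        t2, y2 = integrate_pk(plain, [(0.0, 100.0)], 96.0)
        assert np.allclose(np.interp(t2, t1, y1[1]), y2[1], rtol=1e-8,
                           atol=1e-10)

    def test_gallbladder_trigger_produces_secondary_rise(self):
        dp = tak875_parameters()
        t, y = integrate_pk(dp, [(0.0, 100.0)], 48.0, triggers=(13.0, 19.0))
        conc = y[1] / dp.V_central
        pre = conc[(t > 6.0) & (t <= 13.0)]
        post = conc[(t > 13.05) & (t < 19.0)]
        assert np.any(np.diff(post) > 0.0), "no rise after gallbladder release"
        assert post.max() > pre[-1]

    @pytest.mark.parametrize("fb", [0.0, 0.25, 0.5])
    def test_terminal_recovered_mass_independent_of_biliary_fraction(self, fb):
        dp = replace(tak875_parameters(), biliary_frac=fb, CL=2.0)
        triggers = tuple(24.0 * d + c for d in range(40) for c in (8.0, 13.0, 19.0))
        t, y = integrate_pk(dp, [(0.0, 100.0)], 960.0, triggers=triggers,
                            n_pts=2000)
        assert y[5, -1] == pytest.approx(dp.F * 100.0, rel=1e-3)

    def test_rhs_signature_accepts_meal_times(self):
        dp = tak875_parameters()
        d = tak875_pk_rhs(0.0, PKState("tak875", depot=10.0), dp,
                          meal_times=[8.0, 13.0])
        assert d[0] < 0.0


class TestDoseApplication:
    def test_zero_dose_identity(self):
        pk = PKState("metformin", depot=10.0)
        assert apply_dose(pk, 0.0).depot == 10.0

    def test_additivity_and_split_equivalence(self):
        pk = PKState("metformin", depot=10.0)
        assert apply_dose(pk, 500.0).depot == pytest.approx(510.0)
        split = apply_dose(apply_dose(pk, 250.0), 250.0)
        assert split.depot == pytest.approx(apply_dose(pk, 500.0).depot)

    def test_negative_dose_rejected(self):
        with pytest.raises(DomainError):
            apply_dose(PKState("metformin"), -1.0)

    def test_gallbladder_empty_moves_mass_to_depot(self):
        pk = PKState("tak875", gallbladder=8.0, depot=1.0)
        out = gallbladder_empty(pk, 0.5)
        assert out.gallbladder == pytest.approx(4.0)
        assert out.depot == pytest.approx(5.0)
        assert out.total() == pytest.approx(pk.total())


class TestPdEffects:
    DPS = {"metformin": metformin_parameters(), "tak875": tak875_parameters()}

    def test_drug_free_identity(self):
        eff = pd_effects({"metformin": 0.0, "tak875": 0.0}, self.DPS)
        assert eff.is_identity

    def test_half_max_analytic(self):
        dp = DrugParameters(
            name="metformin", ka=1.0, F=1.0, V_central=10.0,
            V_peripheral=10.0, CL=1.0, Q=1.0,
            effects=(EffectSpec("hepatic_glucose_production", INHIBITION,
                                emax=0.5, ec50=200.0, n=1.0),))
        eff = pd_effects({"metformin": 200.0}, {"metformin": dp})
        assert eff.hepatic_glucose_production == pytest.approx(0.75)

    def test_incretin_hypothesis_gate(self):
        conc = {"tak875": 8000.0}
        off = pd_effects(conc, self.DPS)
        assert off.incretin_secretion_gain == 1.0
        on = pd_effects(conc, self.DPS,
                        {"gpr40_incretin_secretion": True})
        assert on.incretin_secretion_gain > 1.0

    def test_metformin_beta_cell_hypothesis_gate(self):
        conc = {"metformin": 2000.0}
        assert pd_effects(conc, self.DPS).beta_cell_function == 1.0
        on = pd_effects(conc, self.DPS, {"metformin_beta_cell": True})
        assert on.beta_cell_function > 1.0

    def test_multi_drug_effects_multiply_on_shared_tag(self):
        shared = EffectSpec("insulin_secretion_ca_gain", ACTIVATION,
                            emax=1.0, ec50=100.0, n=1.0)
        mk = lambda nm: DrugParameters(name=nm, ka=1, F=1, V_central=10,
                                       V_peripheral=10, CL=1, Q=1,
                                       effects=(shared,))
        dps = {"a": mk("a"), "b": mk("b")}
        one = pd_effects({"a": 100.0, "b": 0.0}, dps)
        both = pd_effects({"a": 100.0, "b": 100.0}, dps)
        assert both.insulin_secretion_ca_gain == pytest.approx(
            one.insulin_secretion_ca_gain**2)

    def test_unknown_drug_rejected(self):
        with pytest.raises(ConfigurationError):
            pd_effects({"mystery": 10.0}, self.DPS)

    def test_pure_function(self):
        conc = {"metformin": 345.6, "tak875": 789.0}
        a = pd_effects(conc, self.DPS)
        b = pd_effects(conc, self.DPS)
        assert a.as_dict() == b.as_dict()

    def test_bounds_across_concentration_sweep(self):
        for c in np.geomspace(0.1, 1e6, 40):
            eff = pd_effects({"metformin": c, "tak875": c}, self.DPS)
            for tag in EFFECT_TAGS:
                assert 0.0 < getattr(eff, tag) <= 4.0


class TestPkMetrics:
    def test_constant_profile(self):
        m = pk_metrics(np.array([0.0, 1.0, 2.0]), np.array([5.0, 5.0, 5.0]))
        assert m == {"Cmax": 5.0, "Tmax": 0.0, "AUC_0_t": 10.0}

    def test_triangle_profile(self):
        m = pk_metrics(np.array([0.0, 2.0, 4.0]), np.array([0.0, 10.0, 0.0]))
        assert m["Cmax"] == 10.0
        assert m["Tmax"] == 2.0
        assert m["AUC_0_t"] == pytest.approx(20.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            pk_metrics(np.array([0.0, 1.0]), np.array([1.0]))

    def test_non_increasing_times_rejected(self):
        with pytest.raises(DomainError):
            pk_metrics(np.array([0.0, 0.0, 1.0]), np.array([1.0, 2.0, 3.0]))
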