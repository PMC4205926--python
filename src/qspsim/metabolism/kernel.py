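"""Scalar numerical kernel of the metabolic ODE system.

:class:`MetabolicKernel` binds one parameter assignment into plain float
attributes once, so the right-hand side evaluates with no dictionary lookups
in the hot loop.  All rate laws live here; the public, validated operations in
:mod:`qspsim.metabolism.fluxes` delegate to this kernel so there is a single
source of truth for the model equations.

Conventions: time h; glucose mM; hormones pM; nutrient pools g; hepatic
metabolite pools mmol; all fluxes mmol/h (glucose) or g/h (nutrients).
"""

from __future__ import annotations

import numpy as np

from ..effects import (
    E_BFUNC, E_CA, E_DELAY, E_FFA, E_GIU, E_HGP, E_INCR, E_MIS,
)
from ..parameters import ParameterSet
from .state import (
    GLUCOSE_MMOL_PER_G,
    GLUCOSE_G_PER_MMOL,
    I_B_FUNC, I_B_MASS, I_C3, I_CPEP, I_FFA, I_G, I_G6P, I_GIP, I_GLP1,
    I_GLY_L, I_GLY_M, I_GN1, I_GN2, I_GUT_CARB, I_GUT_FAT, I_GUT_PROT,
    I_IE_A, I_IE_L, I_IE_M, I_I_PLASMA, I_I_PORTAL, I_S_CA, I_S_CAMP,
    I_ST_CARB, I_ST_FAT, I_ST_PROT, I_TAG_A, I_TAG_P, N_STATE,
)

#: mmol of triacylglycerol per gram (average TAG molar mass ~885 g/mol)
TAG_MMOL_PER_G = 1.13
#: the splanchnic first-pass fraction saturates here however large the
#: GI-utilization multiplier becomes
MAX_SPLANCHNIC_FRAC = 0.95


class MetabolicKernel:
    """Parameter-bound right-hand side of the physiological ODE system."""

    def __init__(self, params: ParameterSet):
        p = params
        self.params = params
        # volumes
        self.v_g = p["vol_glucose"]
        self.v_i = p["vol_insulin"]
        self.v_pl = p["vol_portal"]
        self.v_ffa = p["vol_ffa"]
        self.v_tag = p["vol_tag"]
        # gut
        self.ke_c = p["stomach_empty_carb"]
        self.ke_f = p["stomach_empty_fat"]
        self.ke_p = p["stomach_empty_protein"]
        self.ka_c = p["gut_abs_carb"]
        self.ka_f = p["gut_abs_fat"]
        self.ka_p = p["gut_abs_protein"]
        self.spl_frac = p["splanchnic_uptake_frac"]
        # disposal
        self.brain = p["brain_glucose_uptake"]
        self.gi_vmax = p["gi_uptake_vmax"]
        self.gi_km = p["gi_uptake_km"]
        self.renal_thr = p["renal_threshold"]
        self.renal_slope = p["renal_slope"]
        self.renal_w = p["renal_knee_width"]
        # liver
        self.gk_vmax = p["glucokinase_vmax"]
        self.gk_km = p["glucokinase_km"]
        self.gk_h = p["glucokinase_hill"]
        self.gk_ins = p["glucokinase_insulin_act"]
        self.g6p_rate = p["g6pase_rate"]
        self.gs_rate = p["glycogen_synthesis_rate"]
        self.gs_ins = p["glycogen_synthesis_insulin_act"]
        self.gly_cap = p["glycogen_capacity"]
        self.gl_vmax = p["glycogenolysis_vmax"]
        self.gl_km = p["glycogenolysis_km"]
        self.gl_ins = p["glycogenolysis_insulin_inh"]
        self.gng_vmax = p["gng_vmax"]
        self.gng_km = p["gng_km_c3"]
        self.gng_ins = p["gng_insulin_inh"]
        self.gng_ffa = p["gng_ffa_coeff"]
        self.ffa_ref_h = p["ffa_ref_hepatic"]
        self.gn_ref = p["glucagon_ref"]
        self.gn_stim = p["glucagon_stim_coeff"]
        self.iref_l = p["insulin_ref_liver"]
        self.s_hep = p["hepatic_insulin_sensitivity"]
        # 3-carbon pool
        self.c3_supply = p["c3_endogenous_supply"]
        self.c3_ox = p["c3_oxidation_rate"]
        self.prot_gng = p["protein_gluconeogenic_frac"]
        # muscle
        self.mu_v0 = p["muscle_uptake_basal_vmax"]
        self.mu_vi = p["muscle_uptake_insulin_vmax"]
        self.mu_km = p["muscle_glucose_km"]
        self.iref_m = p["insulin_ref_muscle"]
        self.s_per = p["peripheral_insulin_sensitivity"]
        self.gsm_frac = p["muscle_glycogen_frac"]
        self.glym_cap = p["muscle_glycogen_capacity"]
        self.glym_turn = p["muscle_glycogen_turnover"]
        # adipose glucose
        self.ad_vmax = p["adipose_uptake_vmax"]
        self.ad_ins = p["adipose_insulin_act"]
        self.iref_a = p["insulin_ref_adipose"]
        self.s_adip = p["adipose_insulin_sensitivity"]
        self.glp_ad = p["glp1_adipose_act"]
        self.glp_ad_km = p["glp1_adipose_km"]
        # secretion
        self.sec_vmax = p["secretion_vmax"]
        self.sec_b0 = p["secretion_basal_frac"]
        self.camp_km = p["camp_glucose_km"]
        self.camp_h = p["camp_glucose_hill"]
        self.camp_tau = p["camp_tau"]
        self.w_camp = p["camp_weight"]
        self.ca_km = p["ca_glucose_km"]
        self.ca_h = p["ca_glucose_hill"]
        self.ca_tau = p["ca_tau"]
        self.w_ca = p["ca_weight"]
        self.a_inc = p["incretin_potentiation"]
        self.glp_km = p["glp1_km"]
        self.gip_km = p["gip_km"]
        self.l_ffa = p["beta_ffa_inhibition"]
        self.ffa_ref_b = p["ffa_ref_beta"]
        self.hep_extr = p["hepatic_extraction"]
        self.k_port = p["portal_transfer_rate"]
        self.k_icl = p["insulin_clearance_rate"]
        self.k_cpep = p["cpep_clearance_rate"]
        self.tau_iel = p["ie_tau_liver"]
        self.tau_iem = p["ie_tau_muscle"]
        self.tau_iea = p["ie_tau_adipose"]
        # glucagon
        self.gn_max = p["glucagon_secretion_max"]
        self.gn_gkm = p["glucagon_glucose_km"]
        self.gn_gh = p["glucagon_glucose_hill"]
        self.gn_ikm = p["glucagon_insulin_km"]
        self.gn_cl = p["glucagon_clearance_rate"]
        self.gn_ex = p["glucagon_exchange_rate"]
        # incretins
        self.glp_b = p["glp1_basal_secretion"]
        self.glp_c = p["glp1_meal_coeff"]
        self.glp_cl = p["glp1_clearance"]
        self.gip_b = p["gip_basal_secretion"]
        self.gip_c = p["gip_meal_coeff"]
        self.gip_cl = p["gip_clearance"]
        # lipids
        self.lip_max = p["lipolysis_rate_max"]
        self.lip_ins = p["lipolysis_insulin_inh"]
        self.tag_ref = p["tag_adipose_ref"]
        self.k_fox = p["ffa_oxidation_rate"]
        self.vldl = p["vldl_secretion"]
        self.k_lpl = p["lpl_rate"]
        self.ffa_per_tag = p["ffa_mmol_per_g_tag"]

    # -- component rate laws -------------------------------------------------
    def gut_fluxes(self, gut_c: float, gut_f: float, gut_p: float,
                   delay_factor: float) -> tuple[float, float, float]:
        """Absorption fluxes (g/h) out of the intestinal pools.

        The absorption-delay multiplier (<1 under metformin) slows the
        carbohydrate absorption rate constant; the total eventually absorbed
        is unchanged because absorption is the only exit from the pool.
        """
        return (
            self.ka_c * delay_factor * gut_c,
            self.ka_f * gut_f,
            self.ka_p * gut_p,
        )

    def splanchnic_fraction(self, m_giu: float) -> float:
        return min(MAX_SPLANCHNIC_FRAC, self.spl_frac * m_giu)

    def hepatic_fluxes(self, G: float, G6P: float, Gly: float, C3: float,
                       Gn1: float, FFA: float, ie_l: float,
                       m_hgp: float) -> tuple[float, float, float, float, float]:
        """(glucokinase, G6Pase, glycogen synthesis, glycogenolysis,
        gluconeogenesis), all mmol glucose-equivalents / h.

        Glycogenolysis and gluconeogenesis release glucose directly to plasma
        and carry the hepatic-glucose-production multiplier; glucokinase /
        glycogen synthesis / G6Pase cycle plasma glucose through the G6P pool.
        """
        phi_l = self.s_hep * ie_l / self.iref_l
        f_gn = (1.0 - self.gn_stim) + self.gn_stim * Gn1 / self.gn_ref
        f_ffa = (1.0 - self.gng_ffa) + self.gng_ffa * FFA / self.ffa_ref_h
        Gp = G if G > 0.0 else 0.0
        gh = Gp**self.gk_h
        gk = (self.gk_vmax * gh / (self.gk_km**self.gk_h + gh)
              * (1.0 + self.gk_ins * phi_l))
        cap = 1.0 - Gly / self.gly_cap
        if cap < 0.0:
            cap = 0.0
        gs = self.gs_rate * G6P * (1.0 + self.gs_ins * phi_l) * cap
        g6pase = self.g6p_rate * G6P
        gl = (m_hgp * self.gl_vmax * Gly / (self.gl_km + Gly)
              * f_gn / (1.0 + self.gl_ins * phi_l))
        gng = (m_hgp * self.gng_vmax * C3 / (self.gng_km + C3)
               * f_gn * f_ffa / (1.0 + self.gng_ins * phi_l))
        return gk, g6pase, gs, gl, gng

    def muscle_fluxes(self, G: float, Gly_m: float, ie_m: float,
                      m_mis: float) -> tuple[float, float, float]:
        """(uptake, glycogen synthesis, oxidation), mmol/h.

        Muscle stores and burns glucose but never returns it to plasma; the
        insulin-sensitivity multiplier scales only the insulin-dependent part
        of uptake.
        """
        phi_m = self.s_per * m_mis * ie_m / self.iref_m
        uptake = (self.mu_v0 + self.mu_vi * phi_m) * G / (self.mu_km + G)
        cap = 1.0 - Gly_m / self.glym_cap
        if cap < 0.0:
            cap = 0.0
        gs_m = self.gsm_frac * cap * uptake
        return uptake, gs_m, uptake - gs_m

    def adipose_uptake(self, G: float, ie_a: float, glp1: float,
                       m_mis: float) -> float:
        phi_a = self.s_adip * m_mis * ie_a / self.iref_a
        f_glp = 1.0 + self.glp_ad * glp1 / (self.glp_ad_km + glp1)
        return self.ad_vmax * (1.0 + self.ad_ins * phi_a) * G / (self.mu_km + G) * f_glp

    def brain_uptake(self, G: float) -> float:
        """Constant, insulin-independent consumption; the linear clamp below
        1 mM only guards the integrator against a non-physical zero crossing."""
        return self.brain * (G if G < 1.0 else 1.0)

    def renal_excretion(self, G: float) -> float:
        """Zero below threshold; linear above, with a smooth quadratic knee."""
        x = G - self.renal_thr
        if x <= 0.0:
            return 0.0
        w = self.renal_w
        if x < w:
            return self.renal_slope * x * x / (2.0 * w)
        return self.renal_slope * (x - 0.5 * w)

    def lipolysis(self, tag_a: float, ie_a: float, m_mis: float,
                  m_ffa: float) -> float:
        phi_a = self.s_adip * m_mis * ie_a / self.iref_a
        return (self.lip_max * (tag_a / self.tag_ref) * m_ffa
                / (1.0 + self.lip_ins * phi_a))

    def secretion_rate(self, s_camp: float, s_ca: float, ffa: float,
                       b_mass: float, b_func: float, m_ca: float,
                       m_bf: float) -> float:
        """Insulin secretion (pmol/h); C-peptide is co-released equimolar."""
        f_ffa = 1.0 + self.l_ffa * (1.0 - ffa / self.ffa_ref_b)
        if f_ffa < 0.2:
            f_ffa = 0.2
        elif f_ffa > 3.0:
            f_ffa = 3.0
        drive = (self.sec_b0 + self.w_camp * s_camp
                 + self.w_ca * s_ca * m_ca)
        rate = self.sec_vmax * b_mass * b_func * m_bf * f_ffa * drive
        return rate if rate > 0.0 else 0.0

    def glucagon_secretion(self, G: float, I: float) -> float:
        """Secretion into compartment 1 (pM/h); suppressed by glucose and insulin."""
        g_term = 1.0 + (G / self.gn_gkm) ** self.gn_gh if G > 0.0 else 1.0
        return self.gn_max / g_term / (1.0 + I / self.gn_ikm)

    def beta_signal_targets(self, G: float, glp1: float,
                            gip: float) -> tuple[float, float]:
        """Equilibrium activities of the cAMP and Ca2+ secretion pathways."""
        Gp = G if G > 0.0 else 0.0
        h_camp = Gp**self.camp_h / (self.camp_km**self.camp_h + Gp**self.camp_h)
        h_ca = Gp**self.ca_h / (self.ca_km**self.ca_h + Gp**self.ca_h)
        f_inc = 1.0 + self.a_inc * (glp1 / (self.glp_km + glp1)
                                    + gip / (self.gip_km + gip))
        return h_camp * f_inc, h_ca

    # -- full right-hand side ------------------------------------------------
    def rhs(self, t: float, y: np.ndarray, eff: np.ndarray) -> np.ndarray:
        G = y[I_G]
        st_c, gut_c = y[I_ST_CARB], y[I_GUT_CARB]
        st_f, gut_f = y[I_ST_FAT], y[I_GUT_FAT]
        st_p, gut_p = y[I_ST_PROT], y[I_GUT_PROT]
        G6P, Gly_l, Gly_m = y[I_G6P], y[I_GLY_L], y[I_GLY_M]
        tag_p, ffa, tag_a = y[I_TAG_P], y[I_FFA], y[I_TAG_A]
        c3 = y[I_C3]
        i_port, i_pl, cpep = y[I_I_PORTAL], y[I_I_PLASMA], y[I_CPEP]
        gn1, gn2 = y[I_GN1], y[I_GN2]
        glp1, gip = y[I_GLP1], y[I_GIP]
        s_camp, s_ca = y[I_S_CAMP], y[I_S_CA]
        ie_l, ie_m, ie_a = y[I_IE_L], y[I_IE_M], y[I_IE_A]
        b_mass, b_func = y[I_B_MASS], y[I_B_FUNC]

        m_hgp, m_mis, m_giu, m_delay = eff[E_HGP], eff[E_MIS], eff[E_GIU], eff[E_DELAY]
        m_ffa, m_ca, m_incr, m_bf = eff[E_FFA], eff[E_CA], eff[E_INCR], eff[E_BFUNC]

        dy = np.zeros(N_STATE)

        # gut transit and absorption
        empty_c = self.ke_c * st_c
        empty_f = self.ke_f * st_f
        empty_p = self.ke_p * st_p
        abs_c, abs_f, abs_p = self.gut_fluxes(gut_c, gut_f, gut_p, m_delay)
        dy[I_ST_CARB] = -empty_c
        dy[I_GUT_CARB] = empty_c - abs_c
        dy[I_ST_FAT] = -empty_f
        dy[I_GUT_FAT] = empty_f - abs_f
        dy[I_ST_PROT] = -empty_p
        dy[I_GUT_PROT] = empty_p - abs_p

        ra_mmol = abs_c * GLUCOSE_MMOL_PER_G
        spl = self.splanchnic_fraction(m_giu)
        ra_plasma = ra_mmol * (1.0 - spl)

        # liver
        gk, g6pase, gs, gl, gng = self.hepatic_fluxes(
            G, G6P, Gly_l, c3, gn1, ffa, ie_l, m_hgp)
        dy[I_G6P] = gk - gs - g6pase
        dy[I_GLY_L] = GLUCOSE_G_PER_MMOL * (gs - gl)

        # peripheral disposal
        u_m, gs_m, _ox_m = self.muscle_fluxes(G, Gly_m, ie_m, m_mis)
        dy[I_GLY_M] = GLUCOSE_G_PER_MMOL * gs_m - self.glym_turn * Gly_m
        u_a = self.adipose_uptake(G, ie_a, glp1, m_mis)
        u_b = self.brain_uptake(G)
        u_gi = self.gi_vmax * G / (self.gi_km + G) * m_giu
        e_r = self.renal_excretion(G)

        dy[I_G] = (ra_plasma + g6pase + gl + gng
                   - gk - u_m - u_a - u_b - u_gi - e_r) / self.v_g

        # gluconeogenic substrate pool (glucose-equivalent mmol)
        dy[I_C3] = (self.c3_supply
                    + abs_p * self.prot_gng * GLUCOSE_MMOL_PER_G
                    - gng - self.c3_ox * c3)

        # lipids
        lip = self.lipolysis(tag_a, ie_a, m_mis, m_ffa)
        dy[I_TAG_P] = ((self.vldl + abs_f) * TAG_MMOL_PER_G / self.v_tag
                       - self.k_lpl * tag_p)
        dy[I_FFA] = lip * self.ffa_per_tag / self.v_ffa - self.k_fox * ffa
        dy[I_TAG_A] = 0.0  # store treated as inert on the simulated horizon

        # insulin / C-peptide
        sec = self.secretion_rate(s_camp, s_ca, ffa, b_mass, b_func, m_ca, m_bf)
        dy[I_I_PORTAL] = sec / self.v_pl - self.k_port * i_port
        dy[I_I_PLASMA] = ((1.0 - self.hep_extr) * self.k_port * i_port
                          * self.v_pl / self.v_i - self.k_icl * i_pl)
        dy[I_CPEP] = sec / self.v_i - self.k_cpep * cpep

        # glucagon two-compartment dynamics
        sec_gn = self.glucagon_secretion(G, i_pl)
        dy[I_GN1] = sec_gn - self.gn_cl * gn1 + self.gn_ex * (gn2 - gn1)
        dy[I_GN2] = self.gn_ex * (gn1 - gn2)

        # incretins, driven by carbohydrate absorption
        dy[I_GLP1] = (self.glp_b + self.glp_c * abs_c * m_incr
                      - self.glp_cl * glp1)
        dy[I_GIP] = (self.gip_b + self.gip_c * abs_c * m_incr
                     - self.gip_cl * gip)

        # beta-cell signalling relaxation
        camp_t, ca_t = self.beta_signal_targets(G, glp1, gip)
        dy[I_S_CAMP] = (camp_t - s_camp) / self.camp_tau
        dy[I_S_CA] = (ca_t - s_ca) / self.ca_tau

        # delayed insulin action
        dy[I_IE_L] = (i_pl - ie_l) / self.tau_iel
        dy[I_IE_M] = (i_pl - ie_m) / self.tau_iem
        dy[I_IE_A] = (i_pl - ie_a) / self.tau_iea

        # beta-cell mass/function: constant over <=28-day horizons
        dy[I_B_MASS] = 0.0
        dy[I_B_FUNC] = 0.0
        return dy
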