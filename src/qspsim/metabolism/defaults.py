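"""Baseline parameterization of the metabolic model.

The defaults describe a representative *healthy* adult (normoglycemic fasting
state around 5 mM glucose / 60 pM insulin).  Phenotypes — including the
representative type-2-diabetic used for antidiabetic-therapy studies — are
expressed as virtual-patient overrides on top of this listing, chiefly the
three canonical T2DM defects: hepatic insulin resistance, peripheral insulin
resistance, and reduced beta-cell function.

Rate-law constants without a directly measurable counterpart were calibrated
once so that (i) the healthy fixture has a normoglycemic fasting steady state
with a physiological oral-glucose-tolerance response, and (ii) the T2DM
fixture reproduces its fasting-glucose / OGTT-AUC anchors.  See
``docs/methods.md`` for the calibration account.
"""

from __future__ import annotations

from ..parameters import ParameterDef, ParameterSet

# fmt: off
PARAM_DEFS: tuple[ParameterDef, ...] = (
    # -- distribution volumes ------------------------------------------------
    ParameterDef("vol_glucose", 15.0, "L", "VOLUME", "glucose distribution volume"),
    ParameterDef("vol_insulin", 5.0, "L", "VOLUME", "peripheral insulin distribution volume"),
    ParameterDef("vol_portal", 1.0, "L", "VOLUME", "portal insulin pool volume"),
    ParameterDef("vol_ffa", 10.0, "L", "VOLUME", "free fatty acid distribution volume"),
    ParameterDef("vol_tag", 4.5, "L", "VOLUME", "plasma triacylglycerol volume"),
    # -- gastric emptying and intestinal absorption --------------------------
    ParameterDef("stomach_empty_carb", 1.2, "1/h", "RATE", "gastric emptying, carbohydrate"),
    ParameterDef("stomach_empty_fat", 1.0, "1/h", "RATE", "gastric emptying, fat"),
    ParameterDef("stomach_empty_protein", 1.6, "1/h", "RATE", "gastric emptying, protein"),
    ParameterDef("gut_abs_carb", 1.3, "1/h", "RATE", "intestinal absorption, carbohydrate"),
    ParameterDef("gut_abs_fat", 0.9, "1/h", "RATE", "intestinal absorption, fat"),
    ParameterDef("gut_abs_protein", 1.2, "1/h", "RATE", "intestinal absorption, protein"),
    ParameterDef("bioavail_carb", 1.0, "fraction", "FRACTION", "absorbable fraction of ingested carbohydrate"),
    ParameterDef("bioavail_fat", 0.95, "fraction", "FRACTION", "absorbable fraction of ingested fat"),
    ParameterDef("bioavail_protein", 0.85, "fraction", "FRACTION", "absorbable fraction of ingested protein"),
    ParameterDef("splanchnic_uptake_frac", 0.22, "fraction", "FRACTION", "first-pass splanchnic uptake of absorbed glucose"),
    # -- glucose disposal ----------------------------------------------------
    ParameterDef("brain_glucose_uptake", 33.0, "mmol/h", "RATE", "constant insulin-independent brain uptake"),
    ParameterDef("gi_uptake_vmax", 6.0, "mmol/h", "RATE", "basal GI-tract glucose consumption, Vmax"),
    ParameterDef("gi_uptake_km", 1.5, "mM", "CONC", "basal GI-tract glucose consumption, Km"),
    ParameterDef("renal_threshold", 10.0, "mM", "CONC", "renal glucose reabsorption threshold"),
    ParameterDef("renal_slope", 7.0, "mmol/h/mM", "RATE", "renal excretion slope above threshold"),
    ParameterDef("renal_knee_width", 0.1, "mM", "CONC", "smooth quadratic knee width at the threshold"),
    # -- liver ----------------------------------------------------------------
    ParameterDef("glucokinase_vmax", 45.0, "mmol/h", "RATE", "hepatic glucose phosphorylation Vmax"),
    ParameterDef("glucokinase_km", 10.0, "mM", "CONC", "hepatic glucose phosphorylation Km"),
    ParameterDef("glucokinase_hill", 2.0, "dimensionless", "DIMLESS", "glucokinase cooperativity"),
    ParameterDef("glucokinase_insulin_act", 1.2, "dimensionless", "DIMLESS", "insulin activation of glucokinase"),
    ParameterDef("g6pase_rate", 3.0, "1/h", "RATE", "glucose-6-phosphatase first-order rate"),
    ParameterDef("glycogen_synthesis_rate", 2.0, "1/h", "RATE", "hepatic glycogen synthase rate on G6P"),
    ParameterDef("glycogen_synthesis_insulin_act", 1.0, "dimensionless", "DIMLESS", "insulin activation of glycogen synthesis"),
    ParameterDef("glycogen_capacity", 120.0, "g", "MASS", "hepatic glycogen storage capacity"),
    ParameterDef("glycogenolysis_vmax", 60.0, "mmol/h", "RATE", "glycogen breakdown Vmax"),
    ParameterDef("glycogenolysis_km", 40.0, "g", "MASS", "glycogen breakdown half-saturation store"),
    ParameterDef("glycogenolysis_insulin_inh", 3.0, "dimensionless", "DIMLESS", "insulin inhibition of glycogenolysis"),
    ParameterDef("gng_vmax", 230.0, "mmol/h", "RATE", "gluconeogenesis Vmax"),
    ParameterDef("gng_km_c3", 30.0, "mmol", "CONC", "gluconeogenesis half-saturation on the 3C pool"),
    ParameterDef("gng_insulin_inh", 1.5, "dimensionless", "DIMLESS", "insulin inhibition of gluconeogenesis"),
    ParameterDef("gng_ffa_coeff", 0.3, "dimensionless", "DIMLESS", "FFA drive on gluconeogenesis (0..1)"),
    ParameterDef("ffa_ref_hepatic", 0.5, "mM", "CONC", "reference FFA for the hepatic FFA drive"),
    ParameterDef("glucagon_ref", 20.0, "pM", "HORMONE", "reference glucagon for hepatic stimulation"),
    ParameterDef("glucagon_stim_coeff", 0.5, "dimensionless", "DIMLESS", "glucagon stimulation weight (0..1)"),
    ParameterDef("insulin_ref_liver", 60.0, "pM", "HORMONE", "insulin action normalization at the liver"),
    ParameterDef("hepatic_insulin_sensitivity", 1.0, "dimensionless", "DIMLESS", "hepatic insulin sensitivity scaler"),
    # -- three-carbon gluconeogenic substrate pool ----------------------------
    ParameterDef("c3_endogenous_supply", 70.0, "mmol/h", "RATE", "lumped endogenous 3C substrate supply (lactate/glycerol/amino acids)"),
    ParameterDef("c3_oxidation_rate", 0.8, "1/h", "RATE", "first-order oxidative disposal of the 3C pool"),
    ParameterDef("protein_gluconeogenic_frac", 0.5, "fraction", "FRACTION", "fraction of absorbed protein entering the 3C pool"),
    # -- muscle ----------------------------------------------------------------
    ParameterDef("muscle_uptake_basal_vmax", 10.0, "mmol/h", "RATE", "insulin-independent muscle uptake Vmax"),
    ParameterDef("muscle_uptake_insulin_vmax", 160.0, "mmol/h", "RATE", "insulin-dependent muscle uptake Vmax"),
    ParameterDef("muscle_glucose_km", 9.0, "mM", "CONC", "muscle uptake Km"),
    ParameterDef("insulin_ref_muscle", 400.0, "pM", "HORMONE", "insulin action normalization at muscle"),
    ParameterDef("peripheral_insulin_sensitivity", 1.0, "dimensionless", "DIMLESS", "peripheral (muscle) insulin sensitivity scaler"),
    ParameterDef("muscle_glycogen_frac", 0.6, "fraction", "FRACTION", "maximal fraction of uptake routed to glycogen"),
    ParameterDef("muscle_glycogen_capacity", 400.0, "g", "MASS", "muscle glycogen capacity"),
    ParameterDef("muscle_glycogen_turnover", 0.004, "1/h", "RATE", "basal muscle glycogen utilization"),
    # -- adipose glucose -------------------------------------------------------
    ParameterDef("adipose_uptake_vmax", 3.0, "mmol/h", "RATE", "adipose glucose uptake Vmax"),
    ParameterDef("adipose_insulin_act", 1.0, "dimensionless", "DIMLESS", "insulin activation of adipose uptake"),
    ParameterDef("insulin_ref_adipose", 60.0, "pM", "HORMONE", "insulin action normalization at adipose tissue"),
    ParameterDef("adipose_insulin_sensitivity", 1.0, "dimensionless", "DIMLESS", "adipose insulin sensitivity scaler"),
    ParameterDef("glp1_adipose_act", 0.3, "dimensionless", "DIMLESS", "GLP-1 activation of adipose uptake/oxidation"),
    ParameterDef("glp1_adipose_km", 20.0, "pM", "HORMONE", "GLP-1 half-max for the adipose effect"),
    # -- insulin secretion and clearance --------------------------------------
    ParameterDef("secretion_vmax", 7500.0, "pmol/h", "RATE", "maximal insulin secretion scale"),
    ParameterDef("secretion_basal_frac", 0.05, "fraction", "FRACTION", "glucose-independent basal secretion fraction"),
    ParameterDef("camp_glucose_km", 11.0, "mM", "CONC", "glucose half-max, cAMP pathway"),
    ParameterDef("camp_glucose_hill", 2.0, "dimensionless", "DIMLESS", "glucose Hill coefficient, cAMP pathway"),
    ParameterDef("camp_tau", 0.3, "h", "TIME", "cAMP pathway relaxation time"),
    ParameterDef("camp_weight", 1.0, "dimensionless", "DIMLESS", "cAMP pathway weight in secretion"),
    ParameterDef("ca_glucose_km", 12.0, "mM", "CONC", "glucose half-max, Ca2+ pathway"),
    ParameterDef("ca_glucose_hill", 2.0, "dimensionless", "DIMLESS", "glucose Hill coefficient, Ca2+ pathway"),
    ParameterDef("ca_tau", 0.15, "h", "TIME", "Ca2+ pathway relaxation time"),
    ParameterDef("ca_weight", 1.0, "dimensionless", "DIMLESS", "Ca2+ pathway weight in secretion"),
    ParameterDef("incretin_potentiation", 2.0, "dimensionless", "DIMLESS", "incretin potentiation of the cAMP arm"),
    ParameterDef("glp1_km", 15.0, "pM", "HORMONE", "GLP-1 half-max for potentiation"),
    ParameterDef("gip_km", 40.0, "pM", "HORMONE", "GIP half-max for potentiation"),
    ParameterDef("beta_ffa_inhibition", 0.41, "dimensionless", "DIMLESS", "lipotoxic FFA suppression of secretion"),
    ParameterDef("ffa_ref_beta", 0.6, "mM", "CONC", "reference FFA for beta-cell suppression"),
    ParameterDef("beta_cell_mass", 1.0, "dimensionless", "DIMLESS", "beta-cell mass scaler (constant state)"),
    ParameterDef("beta_cell_function", 1.0, "dimensionless", "DIMLESS", "beta-cell function scaler (constant state)"),
    ParameterDef("hepatic_extraction", 0.5, "fraction", "FRACTION", "first-pass hepatic insulin extraction"),
    ParameterDef("portal_transfer_rate", 20.0, "1/h", "RATE", "portal-to-systemic insulin transfer"),
    ParameterDef("insulin_clearance_rate", 6.0, "1/h", "RATE", "peripheral insulin clearance"),
    ParameterDef("cpep_clearance_rate", 1.4, "1/h", "RATE", "renal C-peptide clearance"),
    # -- insulin action (effect) compartments ---------------------------------
    ParameterDef("ie_tau_liver", 0.3, "h", "TIME", "insulin action delay, liver"),
    ParameterDef("ie_tau_muscle", 0.5, "h", "TIME", "insulin action delay, muscle"),
    ParameterDef("ie_tau_adipose", 0.5, "h", "TIME", "insulin action delay, adipose"),
    # -- glucagon --------------------------------------------------------------
    ParameterDef("glucagon_secretion_max", 90.0, "pM/h", "RATE", "maximal glucagon secretion"),
    ParameterDef("glucagon_glucose_km", 7.0, "mM", "CONC", "glucose half-inhibition of glucagon secretion"),
    ParameterDef("glucagon_glucose_hill", 2.0, "dimensionless", "DIMLESS", "glucose Hill coefficient on glucagon secretion"),
    ParameterDef("glucagon_insulin_km", 150.0, "pM", "HORMONE", "insulin half-inhibition of glucagon secretion"),
    ParameterDef("glucagon_clearance_rate", 2.0, "1/h", "RATE", "glucagon clearance from compartment 1"),
    ParameterDef("glucagon_exchange_rate", 1.0, "1/h", "RATE", "inter-compartment glucagon exchange"),
    # -- incretins -------------------------------------------------------------
    ParameterDef("glp1_basal_secretion", 20.0, "pM/h", "RATE", "basal GLP-1 secretion"),
    ParameterDef("glp1_meal_coeff", 2.5, "pM/g", "RATE", "GLP-1 secretion per g/h of carbohydrate absorption"),
    ParameterDef("glp1_clearance", 4.0, "1/h", "RATE", "GLP-1 clearance"),
    ParameterDef("gip_basal_secretion", 30.0, "pM/h", "RATE", "basal GIP secretion"),
    ParameterDef("gip_meal_coeff", 5.0, "pM/g", "RATE", "GIP secretion per g/h of carbohydrate absorption"),
    ParameterDef("gip_clearance", 3.0, "1/h", "RATE", "GIP clearance"),
    # -- lipids ----------------------------------------------------------------
    ParameterDef("lipolysis_rate_max", 28.0, "g/h", "RATE", "adipose lipolysis at reference store, zero insulin"),
    ParameterDef("lipolysis_insulin_inh", 2.5, "dimensionless", "DIMLESS", "insulin inhibition of lipolysis"),
    ParameterDef("tag_adipose_ref", 12000.0, "g", "MASS", "reference adipose triacylglycerol store"),
    ParameterDef("ffa_oxidation_rate", 5.4, "1/h", "RATE", "FFA oxidation/clearance rate"),
    ParameterDef("vldl_secretion", 1.5, "g/h", "RATE", "hepatic VLDL triacylglycerol secretion"),
    ParameterDef("lpl_rate", 0.38, "1/h", "RATE", "lipoprotein-lipase clearance of plasma TAG"),
    ParameterDef("ffa_mmol_per_g_tag", 3.39, "mmol/g", "DIMLESS", "mmol FFA released per g TAG hydrolysed"),
    # -- meal schedule (defaults; protocols may override) ----------------------
    ParameterDef("meal1_time", 8.0, "h", "TIME", "clock time of meal 1"),
    ParameterDef("meal1_kcal", 600.0, "kcal", "ENERGY", "caloric content of meal 1"),
    ParameterDef("meal2_time", 13.0, "h", "TIME", "clock time of meal 2"),
    ParameterDef("meal2_kcal", 700.0, "kcal", "ENERGY", "caloric content of meal 2"),
    ParameterDef("meal3_time", 19.0, "h", "TIME", "clock time of meal 3"),
    ParameterDef("meal3_kcal", 800.0, "kcal", "ENERGY", "caloric content of meal 3"),
    ParameterDef("meal_carb_frac", 0.45, "fraction", "FRACTION", "carbohydrate energy fraction of meals"),
    ParameterDef("meal_fat_frac", 0.35, "fraction", "FRACTION", "fat energy fraction of meals"),
    ParameterDef("meal_protein_frac", 0.20, "fraction", "FRACTION", "protein energy fraction of meals"),
    # -- anthropometrics (bookkeeping; reported, not dynamic) ------------------
    ParameterDef("body_weight", 75.0, "kg", "MASS", "body weight"),
)
# fmt: on


def build_default_parameters() -> ParameterSet:
    """Fresh :class:`ParameterSet` holding the healthy baseline listing."""
    return ParameterSet(PARAM_DEFS)


#: overrides defining the representative type-2-diabetic phenotype; values are
#: the product of the fixture calibration described in docs/methods.md
T2DM_OVERRIDES: dict[str, float] = {
    "hepatic_insulin_sensitivity": 0.22,
    "peripheral_insulin_sensitivity": 0.45,
    "adipose_insulin_sensitivity": 0.50,
    "beta_cell_function": 0.62,
    "renal_threshold": 11.0,
    "body_weight": 90.0,
}
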