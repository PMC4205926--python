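# Methods

## Scope and shape

`qspsim` couples three layers:

1. a deterministic whole-body model of glucose and lipid metabolism with its
   hormonal regulation, parameterized per *virtual patient* (VP);
2. compartmental PK models for two oral antidiabetic drugs — metformin and
   the GPR40 agonist TAK-875 (fasiglifam) — whose plasma concentrations act
   on the physiology through saturable (Hill) rate multipliers;
3. a model-agnostic simulation manager that treats "complete parameter
   assignment + protocol" as the entire definition of one simulation task
   and fans VP × therapy selections out into batches.

The calibration surface follows the statsmodels idiom: a `MetabolicModel`
bound to a parameter assignment, whose `fit()` returns a
`CalibrationResult` with estimates, residuals and a `summary()` table, and
from which simulations and endpoint extraction hang.

## The metabolic model

**States (28).** Plasma glucose; stomach/intestinal pools for carbohydrate,
fat and protein; hepatic glucose-6-phosphate and glycogen; muscle glycogen;
plasma triacylglycerol (TAG) and free fatty acids (FFA); an inert adipose
TAG store; a lumped three-carbon gluconeogenic substrate pool (lactate,
glycerol, gluconeogenic amino acids, in glucose-equivalent mmol); portal and
peripheral insulin, C-peptide; two glucagon compartments; GLP-1 and GIP;
two dimensionless β-cell signalling activities (cAMP and Ca²⁺ pathway); one
delayed insulin-action state per insulin-sensitive tissue (liver, muscle,
adipose); and constant β-cell mass/function scalers.

**Rate laws.** Where physiology names a saturable process the model uses
Michaelis–Menten or Hill kinetics; transfers and clearances are first
order; regulation enters as dimensionless factors normalized to 1 at the
healthy fasting reference:

* Gut: first-order gastric emptying into an intestinal pool, first-order
  absorption out of it. A fraction of absorbed glucose (default 22%) is
  consumed splanchnically before reaching plasma; drugs can raise this
  fraction (GI glucose utilization) or slow the absorption rate constant
  (delayed, more distal absorption) without changing the amount eventually
  absorbed. Meal bioavailability is applied at ingestion.
* Liver: cooperative glucokinase (Hill 2) feeding a G6P pool that drains to
  glycogen (capacity-limited synthesis) and back to plasma via G6Pase;
  glycogenolysis and gluconeogenesis release glucose directly to plasma,
  are stimulated by glucagon, inhibited by insulin action, and carry the
  hepatic-glucose-production drug multiplier. Gluconeogenesis draws on the
  three-carbon pool (endogenous supply plus dietary protein, with a
  first-order oxidative exit so that regulation, not supply alone, sets the
  flux) and is driven by FFA.
* Disposal: constant insulin-independent brain uptake; basal GI
  consumption; muscle uptake with an insulin-independent and an
  insulin-dependent component (the latter scaled by peripheral sensitivity
  and the drug multiplier), partitioned into capacity-limited glycogen
  storage and oxidation — muscle never returns glucose to plasma; small
  insulin- and GLP-1-sensitive adipose uptake; renal excretion that is zero
  below a threshold and linear above it with a smooth quadratic knee of
  width 0.1 mM (keeps the right-hand side C¹ for the stiff solver).
* Insulin: secretion = scale × β-mass × β-function × (basal + cAMP activity
  × incretin potentiation + Ca²⁺ activity × drug gain) × FFA factor, with
  the two signalling activities relaxing toward glucose-dependent Hill
  targets; equimolar C-peptide co-release; fixed 50% first-pass hepatic
  extraction of portal insulin; first-order peripheral insulin and renal
  C-peptide clearance. The FFA factor (1 at the reference FFA, lower above
  it) encodes lipotoxic suppression of secretion; it is the mechanism by
  which an FFA-lowering drug *raises* fasting insulin while glucose falls.
* Glucagon: secretion suppressed by glucose and insulin into a
  two-compartment system with symmetric exchange (exchange conserves mass;
  only secretion/clearance change the total). Glucagon stimulates
  glycogenolysis and gluconeogenesis.
* Incretins: basal plus absorption-driven secretion of GLP-1 and GIP,
  first-order clearance; both potentiate the cAMP arm of secretion.
* Lipids: insulin-suppressed lipolysis of the adipose store feeds plasma
  FFA (oxidized first order); dietary fat and a constant hepatic VLDL term
  feed plasma TAG, cleared by lipoprotein lipase.

**Held-constant states.** β-cell mass/function and the adipose TAG store
have zero derivative: their intrinsic time scales (months; weeks) are far
beyond the ≤28-day protocols simulated here. Consequently lipid flux into
and out of the adipose store is not mass-conserving against the store — a
deliberate trade that gives the model a true fasting equilibrium on the
simulated horizon.

**Insulin action.** The "multistep" insulin action is realized as one
first-order effect compartment per tissue (time constants 0.3/0.5/0.5 h for
liver/muscle/adipose), i.e. tissues respond to a delayed copy of plasma
insulin.

## Drug models

Both drugs are oral with a gut depot counted as a compartment:
depot → central ↔ peripheral, linear clearance from central. Bioavailability
is applied at administration (depot receives F×dose; (1−F)×dose is recorded
as never absorbed), so recirculated drug is fully reabsorbed and total
cleared mass equals F×dose however the biliary fraction is set.

* Metformin: ka 0.55 h⁻¹, F 0.55, V_c 70 L, V_p 220 L, CL 52 L h⁻¹,
  Q 18 L h⁻¹ — a 500 mg dose peaks near 1 µg/mL at ~1.5 h with a multi-hour
  terminal phase; identical PK is used for healthy and diabetic patients.
* TAK-875: slow-clearance PK (CL 0.4 L h⁻¹, V_c 8 L, V_p 12 L) with
  enterohepatic recirculation: 45% of central elimination routes via a bile
  compartment into the gallbladder, which releases 75% of its content into
  the depot at every meal or glucose-load trigger, producing the
  characteristic meal-locked secondary concentration rises.

**Pharmacodynamics.** Each effect site is an independent Hill multiplier on
one named physiological rate tag; multipliers from different drugs sharing
a tag combine multiplicatively. Metformin acts on hepatic glucose
production (inhibition, emax 0.84, EC50 515 ng/mL, n 2), peripheral insulin
sensitivity (activation, emax 0.05, EC50 515, n 2), GI glucose utilization
(activation, emax 0.545, EC50 16.5, n 1), carbohydrate absorption rate
(inhibition, emax 0.876, EC50 16.5, n 1) and FFA release (inhibition,
emax 0.642, EC50 84.8, n 1.5). TAK-875 amplifies the Ca²⁺ arm of
glucose-stimulated insulin secretion (activation, emax 2, EC50 4000 ng/mL,
n 1.2). Two debated mechanisms sit behind hypothesis switches that default
to off: a direct metformin β-cell effect, and GPR40-driven intestinal
incretin secretion (clinical OGTT data showed no GLP-1/GIP rise, so
reference simulations run with the switch off).

## Protocol conventions

Day 0 is the first dosing day; run-in days (meals only) precede it so the
daily meal cycle has settled before baseline measurements. Fasting
endpoints (FPG, FPI) are interpolated at 07:00, before any dose or meal.
An OGTT is a flagged 75 g carbohydrate-only bolus at 07:00; meals within
3 h of the load are deferred to its end, and doses fall at 09:00/21:00, so
the test runs at trough drug concentration and the day-0 test is drug
free. The OGTT glucose AUC is a *total* trapezoid AUC; the reference-arm
window is 0–2 h, fixed at day-0 calibration and reused for every later
test of the same arm (the generic default window is 3 h and both are
configurable). Meals default to three per day (600/700/800 kcal at
08:00/13:00/19:00; energy fractions 45% carbohydrate, 35% fat, 20%
protein).

## Calibration

**Baseline physiology** was calibrated once: the healthy listing yields a
fasting steady state near 4.8 mM glucose / 60 pM insulin / 0.5 mM FFA with
a normal OGTT excursion, and the representative T2DM overrides (hepatic
sensitivity 0.22, peripheral 0.45, adipose 0.50, β-function 0.62, renal
threshold 11 mM) yield morning FPG ≈ 10.1 mM, fasting insulin ≈ 108 pM,
FFA ≈ 0.64 mM and a day-0 OGTT AUC(0–2 h) ≈ 29.9 mM·h.

**Virtual-patient calibration** (`calibrate_vp` / `MetabolicModel.fit`)
adjusts a small set of free parameters — by default the three canonical
T2DM defects — by damped least squares in log-parameter space with a weak
prior toward the starting phenotype (weight 0.01 per log unit). Targets
using only fasting observables are measured on the drug-free fasting
steady state; when an OGTT AUC target is present all observables are
instead measured on a simulated baseline day (meal run-in, then a morning
OGTT), matching how day-0 endpoints are read in study protocols. The fit
is deterministic (fixed start, fixed optimizer settings) and raises with
its best residual if any target misses by more than 2%. Identifiability
caveat: fasting glucose, fasting insulin and OGTT AUC constrain the
hepatic-vs-peripheral sensitivity split only weakly; fits over that pair
agree in observables while individual values can wander several percent
along the sloppy direction. The parameter-recovery test therefore
exercises the well-identified (hepatic sensitivity, β-function) pair.

**Drug-effect magnitudes** have no independently printed values; the
metformin emax/EC50/n table above (plus the β-cell FFA-sensitivity
coefficient, 0.41) was calibrated once against the reference endpoint
table of the escalating regimen — day 0 anchors the patient, and the day
7/14/28 fasting-glucose, OGTT-AUC and fasting-insulin values constrain the
effect magnitudes — then frozen in the shipped fixtures. The qualitative
structure that makes the table reachable: the gut-acting effects (low
EC50) saturate early and dominate the OGTT AUC reduction already at the
lowest trough, the hepatic effect (high EC50, n 2) produces the late,
dose-graded fasting-glucose decline, and the FFA effect (intermediate
EC50) lifts fasting insulin against the falling-glucose pull, most
strongly at intermediate exposure.

## Numerics

* Integration: LSODA with absolute tolerance 1e-8 and relative 1e-6;
  integration restarts at every discontinuity (meal, dose, glucose load,
  gallbladder trigger), which enter as state jumps; grid samples at an
  event instant carry the pre-jump state. Tiny integrator undershoots of
  pool boundaries are clipped to zero between segments.
* Fasting steady state: input-free pre-integration (400 h, doubled on
  retry) followed by a hybrid-Powell root polish on the non-constant
  states; max |rhs| < 1e-6 or a convergence error carrying the residual.
* A zero-dose regimen prunes its PK block from the state vector, so
  placebo arms are bit-for-bit identical to drug-free simulations.
* Endpoint interpolation is linear on the output grid (default 0.1 h);
  halving the grid moves FPG/AUC by well under 0.5%.

## Problem sizes

The shipped analyses are desk scale by construction: the 28-day escalation
arm (plus 4 run-in days, 0.1 h output grid) integrates in a few seconds;
a full day-0 calibration plus the 28-day prediction completes in well
under a minute; the GPR40 mono/combination battery is eight 15-day
simulations.

## What the synthetic setting does and does not show

All inputs are generated by the package itself (parameter listings, VP
overrides, protocols); there is no patient-level data. Passing tests show
internal consistency — conservation laws, regulation signs, solver
correctness, reproduction of the frozen endpoint table under the stated
conventions — not clinical validity. Known idealizations: meals and doses
are instantaneous; the absorption chain has two pools per nutrient (no
explicit transit compartments); glucagon compartments are phenomenological;
insulin action is a single delay per tissue; no circadian modulation, no
inter-day physiological variability, no β-cell or adipose adaptation
beyond the drug effects; renal threshold behaviour is simplified to a
kneed linear law. Percent-scale agreement with the reference table should
be read accordingly: days 7–28 test the joint calibration of the effect
magnitudes, not out-of-sample prediction.
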