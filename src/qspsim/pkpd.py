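"""Drug pharmacokinetics and pharmacodynamics.

Two oral sub-models are shipped: a linear gut-depot / central / peripheral
compartment model (metformin), and the same topology extended with an
enterohepatic recirculation (EHRC) loop — a fraction of central elimination
is diverted to bile, accumulates in the gallbladder, and is returned to the
gut depot when the gallbladder empties at meal times (the GPR40 agonist
TAK-875, whose clinical profiles show meal-locked secondary peaks).

Bioavailability is applied at administration: the depot receives ``F x dose``
and ``(1 - F) x dose`` is recorded as never absorbed.  Recirculated drug is
therefore fully reabsorbed, and the total mass cleared as t -> infinity is
``F x dose`` for any biliary fraction.

Pharmacodynamics maps plasma concentrations to the dimensionless
:class:`~qspsim.effects.RateMultipliers` through per-site Hill functions;
mechanisms whose clinical support is debated sit behind hypothesis switches
and default to off.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .effects import EFFECT_INDEX, RateMultipliers
from .errors import ConfigurationError, DomainError
from .hill import ACTIVATION, INHIBITION, hill_multiplier
from .parameters import ParameterDef, ParameterSet

ORAL_3C = "oral_3c"
ORAL_EHRC = "oral_ehrc"

#: hypothesis switches and their defaults; all off reproduces the reference
#: simulations (no direct metformin beta-cell effect, no GPR40-driven
#: incretin secretion)
DEFAULT_HYPOTHESES: dict[str, bool] = {
    "metformin_beta_cell": False,
    "gpr40_incretin_secretion": False,
}


@dataclass(frozen=True)
class EffectSpec:
    """One drug effect site: a Hill multiplier keyed to a physiological rate tag."""

    rate_tag: str
    mode: str  # activation | inhibition
    emax: float
    ec50: float  # ng/mL
    n: float = 1.0
    hypothesis: str | None = None  # only active when this switch is on

    def __post_init__(self):
        if self.rate_tag not in EFFECT_INDEX:
            raise ConfigurationError(f"unknown rate tag {self.rate_tag!r}")
        if self.mode not in (ACTIVATION, INHIBITION):
            raise ConfigurationError(f"unknown effect mode {self.mode!r}")


@dataclass(frozen=True)
class DrugParameters:
    """PK constants and PD effect table for one drug."""

    name: str
    model: str = ORAL_3C
    ka: float = 1.0          # 1/h
    F: float = 1.0           # bioavailable fraction
    V_central: float = 10.0  # L
    V_peripheral: float = 10.0
    CL: float = 10.0         # L/h
    Q: float = 5.0           # L/h
    biliary_frac: float = 0.0      # fraction of central elimination to bile
    bile_rate: float = 0.0         # 1/h, bile duct -> gallbladder
    gb_empty_frac: float = 0.0     # fraction released per trigger
    effects: tuple[EffectSpec, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not 0.0 <= self.F <= 1.0:
            raise ConfigurationError(f"{self.name}: F must be in [0, 1]")
        for v, nm in ((self.V_central, "V_central"), (self.V_peripheral, "V_peripheral"),
                      (self.CL, "CL"), (self.Q, "Q"), (self.ka, "ka")):
            if v <= 0.0:
                raise ConfigurationError(f"{self.name}: {nm} must be positive")
        if not 0.0 <= self.biliary_frac <= 1.0:
            raise ConfigurationError(f"{self.name}: biliary_frac must be in [0, 1]")
        if self.model not in (ORAL_3C, ORAL_EHRC):
            raise ConfigurationError(f"{self.name}: unknown PK model {self.model!r}")
        for e in self.effects:
            if e.mode == INHIBITION and e.emax > 1.0:
                raise ConfigurationError(
                    f"{self.name}/{e.rate_tag}: inhibition emax must be <= 1")


@dataclass
class PKState:
    """Per-drug compartment amounts (mg)."""

    drug: str
    depot: float = 0.0
    central: float = 0.0
    peripheral: float = 0.0
    bile: float = 0.0
    gallbladder: float = 0.0
    eliminated: float = 0.0   # cumulative terminal elimination (bookkeeping)

    def validate(self) -> None:
        for nm in ("depot", "central", "peripheral", "bile", "gallbladder", "eliminated"):
            if getattr(self, nm) < 0.0:
                raise DomainError(f"{self.drug}: PK amount {nm} is negative")

    def total(self) -> float:
        return (self.depot + self.central + self.peripheral + self.bile
                + self.gallbladder + self.eliminated)

    def concentration(self, dp: DrugParameters) -> float:
        """Central concentration in ng/mL (mg/L == ug/mL; x1000 -> ng/mL)."""
        return self.central / dp.V_central * 1000.0

    def to_vector(self) -> np.ndarray:
        return np.array([self.depot, self.central, self.peripheral,
                         self.bile, self.gallbladder, self.eliminated])

    @classmethod
    def from_vector(cls, drug: str, v: np.ndarray) -> "PKState":
        return cls(drug, *(float(x) for x in v[:6]))


N_PK_STATE = 6


def pk_rhs_vector(y: np.ndarray, dp: DrugParameters) -> np.ndarray:
    """Shared linear PK right-hand side on the 6-slot vector (mg/h)."""
    depot, central, peripheral, bile = y[0], y[1], y[2], y[3]
    absorb = dp.ka * depot
    c_conc = central / dp.V_central
    p_conc = peripheral / dp.V_peripheral
    exchange = dp.Q * (c_conc - p_conc)
    elim = dp.CL * c_conc
    fb = dp.biliary_frac if dp.model == ORAL_EHRC else 0.0
    to_bile = fb * elim
    cleared = elim - to_bile
    bile_out = dp.bile_rate * bile
    return np.array([
        -absorb,                                  # depot
        absorb - exchange - elim,                 # central
        exchange,                                 # peripheral
        to_bile - bile_out,                       # bile duct
        bile_out,                                 # gallbladder (empties impulsively)
        cleared,                                  # cumulative terminal elimination
    ])


def metformin_pk_rhs(t: float, pk: PKState, dp: DrugParameters) -> np.ndarray:
    """Linear depot/central/peripheral model (derivatives, mg/h)."""
    pk.validate()
    return pk_rhs_vector(pk.to_vector(), dp)


def tak875_pk_rhs(t: float, pk: PKState, dp: DrugParameters,
                  meal_times: list[float] | None = None) -> np.ndarray:
    """EHRC model derivatives (mg/h).

    Gallbladder emptying at meal triggers is impulsive and applied by the
    simulator between segments (see :func:`gallbladder_empty`); the continuous
    part here routes the biliary fraction of elimination through the bile
    duct into the gallbladder.  ``meal_times`` is accepted for interface
    completeness.
    """
    pk.validate()
    return pk_rhs_vector(pk.to_vector(), dp)


def apply_dose(pk: PKState, dose_mg: float, F: float = 1.0) -> PKState:
    """Oral bolus: depot += F x dose; the rest of the state is untouched.

    The never-absorbed fraction is accounted by the caller (simulator), which
    tracks ``(1 - F) x dose`` against the administered total.
    """
    if dose_mg < 0.0:
        raise DomainError(f"dose must be non-negative, got {dose_mg}")
    new = replace(pk)
    new.depot = pk.depot + F * dose_mg
    return new


def gallbladder_empty(pk: PKState, frac: float) -> PKState:
    """Impulsive gallbladder emptying into the gut depot."""
    if not 0.0 <= frac <= 1.0:
        raise DomainError(f"emptying fraction must be in [0, 1], got {frac}")
    released = frac * pk.gallbladder
    new = replace(pk)
    new.gallbladder = pk.gallbladder - released
    new.depot = pk.depot + released
    return new


def pd_effects(
    concentrations: dict[str, float],
    dp_all: dict[str, DrugParameters],
    hypotheses: dict[str, bool] | None = None,
) -> RateMultipliers:
    """Map plasma concentrations (ng/mL) to rate multipliers.

    Pure function: effects from multiple drugs sharing a rate tag combine
    multiplicatively; hypothesis-gated effects contribute 1 unless their
    switch is on; zero concentration contributes exactly 1 everywhere.
    """
    hyp = dict(DEFAULT_HYPOTHESES)
    if hypotheses:
        hyp.update(hypotheses)
    factors = {tag: 1.0 for tag in EFFECT_INDEX}
    for drug, conc in concentrations.items():
        dp = dp_all.get(drug)
        if dp is None:
            raise ConfigurationError(f"no DrugParameters for drug {drug!r}")
        for e in dp.effects:
            if e.hypothesis is not None and not hyp.get(e.hypothesis, False):
                continue
            factors[e.rate_tag] *= hill_multiplier(conc, e.emax, e.ec50, e.n, e.mode)
    return RateMultipliers(**factors)


def pk_metrics(times: np.ndarray, conc: np.ndarray) -> dict[str, float]:
    """Cmax, Tmax (time of first maximum) and trapezoid AUC of a profile."""
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if times.shape != conc.shape:
        raise DomainError("times and conc must have the same length")
    if times.size < 1:
        raise DomainError("empty concentration profile")
    if np.any(np.diff(times) <= 0.0):
        raise DomainError("times must be strictly increasing")
    imax = int(np.argmax(conc))
    auc = float(np.trapezoid(conc, times)) if times.size > 1 else 0.0
    return {"Cmax": float(conc[imax]), "Tmax": float(times[imax]), "AUC_0_t": auc}


# -- shipped drug fixtures ---------------------------------------------------

def metformin_parameters() -> DrugParameters:
    """Metformin PK/PD fixture.

    PK constants give an oral profile peaking ~2.5 h post-dose with a
    multi-hour terminal phase, consistent with published healthy-volunteer
    profiles for 500 mg single and twice-daily dosing; identical PK is used
    for healthy and diabetic phenotypes.  Effect magnitudes are the fixture
    calibration described in docs/methods.md.
    """
    return DrugParameters(
        name="metformin",
        model=ORAL_3C,
        ka=0.55, F=0.55, V_central=70.0, V_peripheral=220.0, CL=52.0, Q=18.0,
        effects=(
            EffectSpec("hepatic_glucose_production", INHIBITION,
                       emax=0.84, ec50=515.0, n=2.0),
            EffectSpec("muscle_insulin_sensitivity", ACTIVATION,
                       emax=0.05, ec50=515.0, n=2.0),
            EffectSpec("gi_glucose_utilization", ACTIVATION,
                       emax=0.545, ec50=16.5, n=1.0),
            EffectSpec("gut_absorption_delay", INHIBITION,
                       emax=0.876, ec50=16.5, n=1.0),
            EffectSpec("ffa_release", INHIBITION,
                       emax=0.642, ec50=84.8, n=1.5),
            EffectSpec("beta_cell_function", ACTIVATION,
                       emax=0.25, ec50=300.0, n=2.0,
                       hypothesis="metformin_beta_cell"),
        ),
    )


def tak875_parameters() -> DrugParameters:
    """GPR40-agonist (TAK-875) PK/PD fixture.

    Long-half-life oral PK with enterohepatic recirculation; the
    pharmacodynamic site is a single net amplification of the Ca2+ arm of
    glucose-stimulated insulin secretion.  GPR40-driven intestinal incretin
    secretion is modelled but gated behind a hypothesis switch (off by
    default, matching the clinical absence of GLP-1/GIP increases).
    """
    return DrugParameters(
        name="tak875",
        model=ORAL_EHRC,
        ka=0.6, F=0.8, V_central=8.0, V_peripheral=12.0, CL=0.4, Q=1.0,
        biliary_frac=0.45, bile_rate=0.8, gb_empty_frac=0.75,
        effects=(
            EffectSpec("insulin_secretion_ca_gain", ACTIVATION,
                       emax=2.0, ec50=4000.0, n=1.2),
            EffectSpec("incretin_secretion_gain", ACTIVATION,
                       emax=1.0, ec50=5000.0, n=1.0,
                       hypothesis="gpr40_incretin_secretion"),
        ),
    )


DRUG_FIXTURES = {
    "metformin": metformin_parameters,
    "tak875": tak875_parameters,
}


# -- parameter-listing integration -------------------------------------------

_PK_FIELDS = ("ka", "F", "V_central", "V_peripheral", "CL", "Q",
              "biliary_frac", "bile_rate", "gb_empty_frac")
_PK_UNITS = {"ka": "1/h", "F": "fraction", "V_central": "L", "V_peripheral": "L",
             "CL": "L/h", "Q": "L/h", "biliary_frac": "fraction",
             "bile_rate": "1/h", "gb_empty_frac": "fraction"}


def drug_parameter_defs(dp: DrugParameters) -> list[ParameterDef]:
    """Flatten a drug's numeric constants into parameter definitions so the
    full simulation-task listing exposes them by name."""
    defs = [
        ParameterDef(f"{dp.name}_{f}", getattr(dp, f), _PK_UNITS[f],
                     "FRACTION" if _PK_UNITS[f] == "fraction" else "RATE",
                     f"{dp.name} PK constant {f}")
        for f in _PK_FIELDS
    ]
    for e in dp.effects:
        stem = f"{dp.name}_eff_{e.rate_tag}"
        defs.append(ParameterDef(f"{stem}_emax", e.emax, "dimensionless", "DIMLESS",
                                 f"{dp.name} {e.mode} emax on {e.rate_tag}"))
        defs.append(ParameterDef(f"{stem}_ec50", e.ec50, "ng/mL", "CONC",
                                 f"{dp.name} ec50 on {e.rate_tag}"))
        defs.append(ParameterDef(f"{stem}_n", e.n, "dimensionless", "DIMLESS",
                                 f"{dp.name} Hill coefficient on {e.rate_tag}"))
    return defs


def drug_from_parameterset(ps: ParameterSet, template: DrugParameters) -> DrugParameters:
    """Rebuild :class:`DrugParameters` from a listing that carries the
    flattened names produced by :func:`drug_parameter_defs`; structural fields
    (model topology, effect modes, hypothesis gates) come from the template."""
    kwargs = {f: ps[f"{template.name}_{f}"] for f in _PK_FIELDS}
    effects = tuple(
        EffectSpec(e.rate_tag, e.mode,
                   emax=ps[f"{template.name}_eff_{e.rate_tag}_emax"],
                   ec50=ps[f"{template.name}_eff_{e.rate_tag}_ec50"],
                   n=ps[f"{template.name}_eff_{e.rate_tag}_n"],
                   hypothesis=e.hypothesis)
        for e in template.effects
    )
    return replace(template, effects=effects, **kwargs)
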