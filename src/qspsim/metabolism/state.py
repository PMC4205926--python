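"""State vector of the whole-body metabolic model.

The physiology is a deterministic ODE system over the pools drawn in the
model's block diagram: gut nutrient pools, plasma glucose, hepatic
glucose-6-phosphate and glycogen, muscle glycogen, plasma lipids, the
insulin/C-peptide/glucagon/incretin hormone system, and the beta-cell
signalling activities that couple plasma glucose to insulin secretion.

Meals, oral glucose loads and drug doses are *not* continuous inputs: they
enter as instantaneous state jumps applied by the simulator between
integration segments, so the right-hand side itself is autonomous apart from
the drug rate multipliers.

Index constants (``I_*``) address the flat ``numpy`` vector used by the
numerical kernels; :class:`MetabolicState` is the named, unit-annotated view.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from ..errors import DomainError

# -- state vector layout ----------------------------------------------------
I_G = 0           # plasma glucose (mM)
I_ST_CARB = 1     # stomach carbohydrate (g)
I_GUT_CARB = 2    # intestinal carbohydrate (g)
I_ST_FAT = 3      # stomach fat (g)
I_GUT_FAT = 4     # intestinal fat (g)
I_ST_PROT = 5     # stomach protein (g)
I_GUT_PROT = 6    # intestinal protein (g)
I_G6P = 7         # hepatic glucose-6-phosphate (mmol)
I_GLY_L = 8       # hepatic glycogen (g)
I_GLY_M = 9       # muscle glycogen (g)
I_TAG_P = 10      # plasma triacylglycerol (mM)
I_FFA = 11        # plasma free fatty acids (mM)
I_TAG_A = 12      # adipose triacylglycerol store (g); inert on <=28 d horizon
I_C3 = 13         # gluconeogenic three-carbon substrate pool (glucose-equivalent mmol)
I_I_PORTAL = 14   # portal insulin (pM)
I_I_PLASMA = 15   # peripheral plasma insulin (pM)
I_CPEP = 16       # plasma C-peptide (pM)
I_GN1 = 17        # glucagon, central compartment (pM)
I_GN2 = 18        # glucagon, exchange compartment (pM)
I_GLP1 = 19       # glucagon-like peptide-1 (pM)
I_GIP = 20        # gastric inhibitory peptide (pM)
I_S_CAMP = 21     # beta-cell cAMP pathway activity (dimensionless)
I_S_CA = 22       # beta-cell Ca2+ pathway activity (dimensionless)
I_IE_L = 23       # delayed insulin action at the liver (pM)
I_IE_M = 24       # delayed insulin action at muscle (pM)
I_IE_A = 25       # delayed insulin action at adipose tissue (pM)
I_B_MASS = 26     # beta-cell mass scaler (dimensionless, constant)
I_B_FUNC = 27     # beta-cell function scaler (dimensionless, constant)

N_STATE = 28

STATE_NAMES: tuple[str, ...] = (
    "G_plasma", "stomach_carb", "gut_carb", "stomach_fat", "gut_fat",
    "stomach_protein", "gut_protein", "G6P_liver", "Gly_liver", "Gly_muscle",
    "TAG_plasma", "FFA_plasma", "TAG_adipose", "C3_pool", "I_portal",
    "I_plasma", "Cpep", "Gn_1", "Gn_2", "GLP1", "GIP", "S_camp", "S_ca",
    "IE_liver", "IE_muscle", "IE_adipose", "B_mass", "B_func",
)

STATE_UNITS: tuple[str, ...] = (
    "mM", "g", "g", "g", "g", "g", "g", "mmol", "g", "g",
    "mM", "mM", "g", "mmol", "pM", "pM", "pM", "pM", "pM", "pM", "pM",
    "dimensionless", "dimensionless", "pM", "pM", "pM",
    "dimensionless", "dimensionless",
)

#: grams of glucose per mmol (and its inverse), used wherever nutrient mass
#: (g) meets plasma fluxes (mmol/h)
GLUCOSE_G_PER_MMOL = 0.18016
GLUCOSE_MMOL_PER_G = 1.0 / GLUCOSE_G_PER_MMOL

#: energy densities (kcal/g) used to turn a meal's caloric content into grams
KCAL_PER_G = {"carb": 4.0, "fat": 9.0, "protein": 4.0}


@dataclass
class MetabolicState:
    """Named view of the physiological state vector at one time point."""

    t: float = 0.0
    G_plasma: float = 5.0
    stomach_carb: float = 0.0
    gut_carb: float = 0.0
    stomach_fat: float = 0.0
    gut_fat: float = 0.0
    stomach_protein: float = 0.0
    gut_protein: float = 0.0
    G6P_liver: float = 2.0
    Gly_liver: float = 40.0
    Gly_muscle: float = 200.0
    TAG_plasma: float = 1.0
    FFA_plasma: float = 0.5
    TAG_adipose: float = 12000.0
    C3_pool: float = 30.0
    I_portal: float = 180.0
    I_plasma: float = 60.0
    Cpep: float = 500.0
    Gn_1: float = 20.0
    Gn_2: float = 20.0
    GLP1: float = 5.0
    GIP: float = 10.0
    S_camp: float = 0.4
    S_ca: float = 0.3
    IE_liver: float = 60.0
    IE_muscle: float = 60.0
    IE_adipose: float = 60.0
    B_mass: float = 1.0
    B_func: float = 1.0

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, y: np.ndarray, t: float = 0.0) -> "MetabolicState":
        y = np.asarray(y, dtype=float)
        if y.shape[0] < N_STATE:
            raise DomainError(
                f"state vector has length {y.shape[0]}, expected >= {N_STATE}"
            )
        return cls(t=t, **{n: float(y[i]) for i, n in enumerate(STATE_NAMES)})

    def validate(self) -> None:
        """Check non-negativity and finiteness of every pool.

        Physiological states keep the beta-cell scalers strictly positive; a
        zero scaler is admitted as the degenerate no-secretion limit.
        """
        for f in fields(self):
            if f.name == "t":
                continue
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise DomainError(f"state field {f.name} is non-finite")
            if v < 0.0:
                raise DomainError(f"state field {f.name} is negative ({v})")
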