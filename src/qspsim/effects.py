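"""Dimensionless drug-effect multipliers on physiological rates.

Pharmacodynamics enters the metabolic model exclusively through this small
set of named multipliers.  Each tag scales one mechanistic site; with no drug
on board every multiplier is exactly 1 and the physiology is bit-for-bit the
drug-free model.  Inhibition-type factors live in (0, 1]; activation-type
factors in [1, 1 + emax].
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .errors import ConfigurationError

#: rate tags, in kernel order
EFFECT_TAGS: tuple[str, ...] = (
    "hepatic_glucose_production",   # scales glycogenolysis + gluconeogenesis
    "muscle_insulin_sensitivity",   # scales insulin-dependent peripheral uptake
    "gi_glucose_utilization",       # scales splanchnic/GI glucose consumption
    "gut_absorption_delay",         # <1 slows carbohydrate absorption kinetics
    "ffa_release",                  # scales adipose lipolysis
    "insulin_secretion_ca_gain",    # amplifies the Ca2+ arm of secretion
    "incretin_secretion_gain",      # scales meal-driven GLP-1/GIP secretion
    "beta_cell_function",           # scales overall secretory capacity
)

E_HGP, E_MIS, E_GIU, E_DELAY, E_FFA, E_CA, E_INCR, E_BFUNC = range(8)
N_EFFECTS = len(EFFECT_TAGS)

EFFECT_INDEX = {tag: i for i, tag in enumerate(EFFECT_TAGS)}


@dataclass
class RateMultipliers:
    """One multiplier per physiological rate tag (all 1.0 = drug free)."""

    hepatic_glucose_production: float = 1.0
    muscle_insulin_sensitivity: float = 1.0
    gi_glucose_utilization: float = 1.0
    gut_absorption_delay: float = 1.0
    ffa_release: float = 1.0
    insulin_secretion_ca_gain: float = 1.0
    incretin_secretion_gain: float = 1.0
    beta_cell_function: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, t) for t in EFFECT_TAGS], dtype=float)

    @classmethod
    def from_mapping(cls, mapping: dict[str, float]) -> "RateMultipliers":
        """Build from a complete tag -> factor map; missing tags are an error."""
        missing = [t for t in EFFECT_TAGS if t not in mapping]
        if missing:
            raise ConfigurationError(f"missing rate multiplier tag(s): {', '.join(missing)}")
        unknown = sorted(set(mapping) - set(EFFECT_TAGS))
        if unknown:
            raise ConfigurationError(f"unknown rate multiplier tag(s): {', '.join(unknown)}")
        return cls(**mapping)

    def as_dict(self) -> dict[str, float]:
        return {t: getattr(self, t) for t in EFFECT_TAGS}

    @property
    def is_identity(self) -> bool:
        return all(getattr(self, f.name) == 1.0 for f in fields(self))


IDENTITY_EFFECTS = RateMultipliers()
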