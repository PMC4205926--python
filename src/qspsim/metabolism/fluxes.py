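"""Public, validated operations of the metabolic model.

Thin wrappers over :class:`~qspsim.metabolism.kernel.MetabolicKernel`: they
accept the named :class:`MetabolicState`, validate domains, and return named
fluxes.  The numerical content is identical to what the integrator sees.
"""

from __future__ import annotations

import numpy as np

from ..effects import E_BFUNC, E_CA, E_DELAY, E_FFA, E_GIU, E_HGP, E_MIS, RateMultipliers
from ..errors import ConfigurationError, DomainError
from ..parameters import ParameterSet
from .kernel import MetabolicKernel
from .state import MetabolicState, N_STATE, STATE_NAMES


def _effects_array(effects: RateMultipliers | dict) -> np.ndarray:
    if isinstance(effects, dict):
        effects = RateMultipliers.from_mapping(effects)
    if not isinstance(effects, RateMultipliers):
        raise ConfigurationError(
            f"effects must be RateMultipliers or a complete tag map, got {type(effects)!r}")
    return effects.as_array()


def metabolic_rhs(
    t: float,
    state: MetabolicState,
    params: ParameterSet,
    effects: RateMultipliers | dict,
    inputs=None,
) -> np.ndarray:
    """Time derivative of every state field (same order as ``STATE_NAMES``).

    Meals, glucose loads and doses are impulsive inputs applied between
    integration segments, so ``inputs`` (the protocol) does not contribute a
    continuous term here; it is accepted for interface completeness.
    """
    state.validate()
    eff = _effects_array(effects)
    kern = MetabolicKernel(params)
    dy = kern.rhs(t, state.to_vector(), eff)
    if not np.all(np.isfinite(dy)):
        bad = [STATE_NAMES[i] for i in range(N_STATE) if not np.isfinite(dy[i])]
        raise DomainError(f"non-finite derivative(s) for: {', '.join(bad)}")
    return dy


def gut_absorption_flux(
    t: float,
    state: MetabolicState,
    params: ParameterSet,
    delay_factor: float = 1.0,
) -> dict[str, float]:
    """Nutrient appearance rates out of the gut (g/h per macronutrient)."""
    if delay_factor <= 0.0:
        raise DomainError(f"delay_factor must be positive, got {delay_factor}")
    for name in ("gut_carb", "gut_fat", "gut_protein"):
        if getattr(state, name) < 0.0:
            raise DomainError(f"{name} must be non-negative")
    kern = MetabolicKernel(params)
    c, f, p = kern.gut_fluxes(state.gut_carb, state.gut_fat, state.gut_protein,
                              delay_factor)
    return {"carb": c, "fat": f, "protein": p}


def hepatic_glucose_fluxes(
    state: MetabolicState,
    params: ParameterSet,
    effects: RateMultipliers | dict,
) -> dict[str, float]:
    """Named hepatic fluxes (mmol/h).

    ``glycogenolysis`` and ``gluconeogenesis`` release glucose to plasma and
    are scaled by the hepatic-glucose-production multiplier; ``glucokinase``,
    ``glycogen_synthesis`` and ``G6Pase`` cycle through the G6P pool.
    """
    state.validate()
    eff = _effects_array(effects)
    kern = MetabolicKernel(params)
    gk, g6pase, gs, gl, gng = kern.hepatic_fluxes(
        state.G_plasma, state.G6P_liver, state.Gly_liver, state.C3_pool,
        state.Gn_1, state.FFA_plasma, state.IE_liver, eff[E_HGP])
    return {
        "glucokinase": gk,
        "G6Pase": g6pase,
        "glycogen_synthesis": gs,
        "glycogenolysis": gl,
        "gluconeogenesis": gng,
    }


def muscle_glucose_dynamics(
    state: MetabolicState,
    params: ParameterSet,
    effects: RateMultipliers | dict,
) -> dict[str, float]:
    """Muscle glucose fluxes (mmol/h): uptake, glycogen synthesis, oxidation.

    There is deliberately no flux from muscle glycogen back to plasma glucose.
    """
    state.validate()
    eff = _effects_array(effects)
    kern = MetabolicKernel(params)
    uptake, gs_m, ox = kern.muscle_fluxes(
        state.G_plasma, state.Gly_muscle, state.IE_muscle, eff[E_MIS])
    return {"uptake": uptake, "glycogen_synthesis": gs_m, "oxidation": ox}


def renal_glucose_excretion(G_plasma: float, params: ParameterSet) -> float:
    """Urinary glucose loss (mmol/h): zero until the reabsorption threshold,
    then linear with a smooth quadratic knee."""
    if G_plasma < 0.0:
        raise DomainError(f"G_plasma must be non-negative, got {G_plasma}")
    return MetabolicKernel(params).renal_excretion(G_plasma)


def insulin_secretion_rate(
    state: MetabolicState,
    params: ParameterSet,
    effects: RateMultipliers | dict,
) -> float:
    """Insulin secretion (pmol/h); C-peptide is co-released equimolar."""
    state.validate()
    eff = _effects_array(effects)
    kern = MetabolicKernel(params)
    return kern.secretion_rate(state.S_camp, state.S_ca, state.FFA_plasma,
                               state.B_mass, state.B_func, eff[E_CA],
                               eff[E_BFUNC])


def glucagon_dynamics(
    state: MetabolicState,
    params: ParameterSet,
) -> tuple[float, float]:
    """Derivatives (pM/h) of the two glucagon compartments."""
    state.validate()
    kern = MetabolicKernel(params)
    sec = kern.glucagon_secretion(state.G_plasma, state.I_plasma)
    d1 = sec - kern.gn_cl * state.Gn_1 + kern.gn_ex * (state.Gn_2 - state.Gn_1)
    d2 = kern.gn_ex * (state.Gn_1 - state.Gn_2)
    return d1, d2
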