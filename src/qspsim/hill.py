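"""Saturable concentration-effect (Hill/Emax) multipliers.

Drug effects enter the physiology as dimensionless multipliers on rate
equations.  An *activation* multiplier runs from 1 at zero concentration to
``1 + emax`` at saturation; an *inhibition* multiplier runs from 1 down to
``1 - emax`` (so ``emax <= 1`` keeps rates non-negative).
"""

from __future__ import annotations

from .errors import DomainError

ACTIVATION = "activation"
INHIBITION = "inhibition"


def hill_multiplier(C: float, emax: float, ec50: float, n: float, mode: str) -> float:
    """Dimensionless rate multiplier for drug concentration ``C``.

    Parameters
    ----------
    C : concentration, same units as ``ec50`` (negative C is a domain error).
    emax : maximal fractional effect; for inhibition must not exceed 1.
    ec50 : half-maximal concentration, > 0.
    n : Hill coefficient, > 0.
    mode : ``"activation"`` or ``"inhibition"``.
    """
    if ec50 <= 0.0:
        raise DomainError(f"ec50 must be positive, got {ec50}")
    if n <= 0.0:
        raise DomainError(f"Hill coefficient must be positive, got {n}")
    if emax < 0.0:
        raise DomainError(f"emax must be non-negative, got {emax}")
    if C < 0.0:
        raise DomainError(f"concentration must be non-negative, got {C}")
    if mode == INHIBITION and emax > 1.0:
        raise DomainError(f"inhibition emax must be <= 1, got {emax}")
    if mode not in (ACTIVATION, INHIBITION):
        raise DomainError(f"mode must be 'activation' or 'inhibition', got {mode!r}")
    if C == 0.0:
        return 1.0
    occ = C**n / (ec50**n + C**n)
    if mode == ACTIVATION:
        return 1.0 + emax * occ
    return 1.0 - emax * occ
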