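"""Fasting steady state of the metabolic model.

With no meals and no drugs the physiology relaxes to a unique fasting
equilibrium (the model's fasting plasma glucose / insulin / lipid baselines).
The solver integrates the input-free system for several hundred hours to get
into the equilibrium's basin, then polishes with a damped root find on the
right-hand side.  Deterministic for fixed parameters.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from ..effects import IDENTITY_EFFECTS, RateMultipliers
from ..errors import ConvergenceError
from ..parameters import ParameterSet
from .kernel import MetabolicKernel
from .state import I_B_FUNC, I_B_MASS, I_TAG_A, MetabolicState, N_STATE

#: states held constant on the simulated horizon (identically zero derivative)
_CONST_IDX = (I_TAG_A, I_B_MASS, I_B_FUNC)
_FREE_IDX = np.array([i for i in range(N_STATE) if i not in _CONST_IDX])


def initial_state(params: ParameterSet) -> MetabolicState:
    """Generic pre-integration starting point for the given parameters."""
    s = MetabolicState()
    s.TAG_adipose = params["tag_adipose_ref"]
    s.B_mass = params["beta_cell_mass"]
    s.B_func = params["beta_cell_function"]
    return s


def steady_state(
    params: ParameterSet,
    effects: RateMultipliers = IDENTITY_EFFECTS,
    tol: float = 1e-6,
    pre_hours: float = 400.0,
    start: MetabolicState | None = None,
) -> MetabolicState:
    """Input-free fasting equilibrium with ``max |rhs| < tol``.

    Raises
    ------
    ConvergenceError
        If the residual stays above ``tol`` after the pre-integration fallback
        budget is exhausted; the error carries the best residual reached.
    """
    kern = MetabolicKernel(params)
    eff = effects.as_array()
    y = (start if start is not None else initial_state(params)).to_vector()

    def rhs(t, yv):
        return kern.rhs(t, yv, eff)

    def reduced_residual(y_free):
        yf = y_const.copy()
        yf[_FREE_IDX] = y_free
        return kern.rhs(0.0, yf, eff)[_FREE_IDX]

    best_res = np.inf
    best_y = y
    hours = pre_hours
    for _ in range(4):
        sol = solve_ivp(rhs, (0.0, hours), y, method="LSODA",
                        rtol=1e-8, atol=1e-10, dense_output=False)
        y = sol.y[:, -1]
        y_const = y.copy()
        polish = root(reduced_residual, y[_FREE_IDX], method="hybr",
                      options={"xtol": 1e-12})
        y_try = y_const.copy()
        y_try[_FREE_IDX] = polish.x
        res = float(np.max(np.abs(kern.rhs(0.0, y_try, eff))))
        if res < best_res and np.all(y_try[_FREE_IDX] > -1e-9):
            best_res, best_y = res, np.clip(y_try, 0.0, None)
        if best_res < tol:
            return MetabolicState.from_vector(best_y)
        hours *= 2.0
    raise ConvergenceError(
        f"fasting steady state did not converge (best max|rhs| = {best_res:.3e})",
        residual=best_res,
    )
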