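"""Model / Results surface for calibration and simulation.

:class:`MetabolicModel` wraps one parameterization of the physiology the way
statistical packages wrap a model bound to data: construct it from a
parameter listing or virtual patient, ``fit()`` it to clinical anchor values
to obtain a :class:`CalibrationResult` (estimates, residuals, a ``summary()``
table), and ``simulate()`` protocols from either object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metabolism import MetabolicState, build_default_parameters, steady_state
from .metabolism.defaults import T2DM_OVERRIDES
from .parameters import ParameterSet
from .pkpd import DrugParameters
from .protocols import Endpoints, Protocol, compute_endpoints
from .results import TimeSeriesResult
from .simulate import simulate
from .vpatients import (
    DEFAULT_FREE_PARAMS, VirtualPatient, calibrate_vp, measure_observables,
)


class MetabolicModel:
    """Whole-body metabolic model bound to one parameter assignment."""

    def __init__(self, params: ParameterSet | None = None,
                 drugs: dict[str, DrugParameters] | None = None,
                 hypotheses: dict[str, bool] | None = None):
        self.params = params if params is not None else build_default_parameters()
        self.drugs = drugs
        self.hypotheses = hypotheses

    # -- constructors --------------------------------------------------------
    @classmethod
    def healthy(cls, **kw) -> "MetabolicModel":
        return cls(build_default_parameters(), **kw)

    @classmethod
    def t2dm(cls, **kw) -> "MetabolicModel":
        """Representative type-2-diabetes phenotype fixture."""
        return cls(build_default_parameters().with_overrides(T2DM_OVERRIDES), **kw)

    @classmethod
    def from_virtual_patient(cls, vp: VirtualPatient,
                             base: ParameterSet | None = None,
                             **kw) -> "MetabolicModel":
        return cls(vp.resolve(base), **kw)

    # -- computation ---------------------------------------------------------
    def steady_state(self, **kw) -> MetabolicState:
        return steady_state(self.params, **kw)

    def simulate(self, protocol: Protocol,
                 start: MetabolicState | None = None, **kw) -> TimeSeriesResult:
        return simulate(self.params, protocol, drugs=self.drugs,
                        hypotheses=self.hypotheses, start=start, **kw)

    def endpoints(self, protocol: Protocol, days,
                  start: MetabolicState | None = None,
                  reference_day: int | None = 0) -> dict[int, Endpoints]:
        res = self.simulate(protocol, start=start)
        return {d: compute_endpoints(res, protocol, d, reference_day)
                for d in days}

    def fit(self, targets: dict[str, float],
            free_params: tuple[str, ...] = DEFAULT_FREE_PARAMS,
            **kw) -> "CalibrationResult":
        """Calibrate ``free_params`` to clinical anchors (see
        :func:`qspsim.vpatients.calibrate_vp` for target names and method)."""
        vp = calibrate_vp(targets, free_params=free_params, base=self.params,
                          **kw)
        fitted = self.params.with_overrides(
            {k: vp.overrides[k] for k in free_params})
        achieved = measure_observables(
            fitted, targets,
            auc_window=kw.get("auc_window", 2.0),
            run_in_days=kw.get("run_in_days", 4))
        return CalibrationResult(
            model=self, params=fitted, vp=vp, targets=dict(targets),
            achieved=achieved,
            estimates={k: vp.overrides[k] for k in free_params},
            start_values={k: self.params[k] for k in free_params},
        )


@dataclass
class CalibrationResult:
    """Outcome of a virtual-patient calibration."""

    model: MetabolicModel
    params: ParameterSet
    vp: VirtualPatient
    targets: dict[str, float]
    achieved: dict[str, float]
    estimates: dict[str, float]
    start_values: dict[str, float] = field(default_factory=dict)

    @property
    def residuals(self) -> dict[str, float]:
        """Relative target residuals (achieved vs requested)."""
        return {k: (self.achieved[k] - v) / v for k, v in self.targets.items()}

    @property
    def max_abs_residual(self) -> float:
        return max(abs(r) for r in self.residuals.values())

    def as_model(self) -> MetabolicModel:
        """Calibrated model carrying the same drug/hypothesis bindings."""
        return MetabolicModel(self.params, drugs=self.model.drugs,
                              hypotheses=self.model.hypotheses)

    def simulate(self, protocol: Protocol, **kw) -> TimeSeriesResult:
        return self.as_model().simulate(protocol, **kw)

    def endpoints(self, protocol: Protocol, days, **kw) -> dict[int, Endpoints]:
        return self.as_model().endpoints(protocol, days, **kw)

    def summary(self) -> str:
        """Human-readable calibration report."""
        lines = [
            "Virtual-patient calibration",
            "=" * 61,
            f"{'parameter':<34}{'start':>12}{'fitted':>12}",
            "-" * 61,
        ]
        for k, v in self.estimates.items():
            s = self.start_values.get(k, float("nan"))
            lines.append(f"{k:<34}{s:>12.4g}{v:>12.4g}")
        lines.append("-" * 61)
        lines.append(f"{'target':<22}{'requested':>12}{'achieved':>12}{'resid':>12}")
        lines.append("-" * 61)
        for k, v in self.targets.items():
            lines.append(
                f"{k:<22}{v:>12.4g}{self.achieved[k]:>12.4g}"
                f"{self.residuals[k]:>+12.2%}")
        lines.append("=" * 61)
        return "\n".join(lines)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.summary()
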