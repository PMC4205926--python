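"""Shipped model plugins.

The metabolic plugin exposes the whole-body model through the manager's
model-agnostic contract: its listing is the physiological parameters plus the
flattened PK/PD constants of both shipped drugs, and its entry point is a
module-level function (so batches can run in worker processes).

A deliberately trivial one-compartment decay plugin demonstrates (and tests)
that the manager is independent of model specifics.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .metabolism import build_default_parameters
from .metabolism.defaults import PARAM_DEFS
from .manager import ModelPlugin
from .parameters import ParameterDef, ParameterSet
from .pkpd import (
    drug_from_parameterset, drug_parameter_defs, metformin_parameters,
    tak875_parameters,
)
from .protocols import Protocol
from .results import TimeSeriesResult
from .simulate import simulate

METABOLIC_MODEL_ID = "metabolic-t2dm-v1"
TOY_MODEL_ID = "toy-decay-v1"


def metabolic_parameter_listing() -> ParameterSet:
    """Physiology + flattened drug constants: the plugin's full input listing."""
    defs = list(PARAM_DEFS)
    defs += drug_parameter_defs(metformin_parameters())
    defs += drug_parameter_defs(tak875_parameters())
    return ParameterSet(defs)


def _metabolic_entry(assignment: dict, protocol: Protocol,
                     output_spec: tuple) -> TimeSeriesResult:
    listing = metabolic_parameter_listing()
    full = listing.update_from_text(
        "\n".join(f"{k}\t{v!r}" for k, v in assignment.items()))
    phys = build_default_parameters()
    phys = phys.with_overrides({n: full[n] for n in phys.names()})
    drugs = {
        "metformin": drug_from_parameterset(full, metformin_parameters()),
        "tak875": drug_from_parameterset(full, tak875_parameters()),
    }
    if output_spec:
        protocol = type(protocol)(**{**protocol.__dict__,
                                     "outputs": tuple(output_spec)})
    return simulate(phys, protocol, drugs=drugs)


def build_metabolic_plugin() -> ModelPlugin:
    return ModelPlugin(model_id=METABOLIC_MODEL_ID,
                       parameters=metabolic_parameter_listing(),
                       entry_point=_metabolic_entry)


# -- toy fixture plugin --------------------------------------------------------

_TOY_DEFS = (
    ParameterDef("y0", 1.0, "dimensionless", "DIMLESS", "initial amount"),
    ParameterDef("k_decay", 0.5, "1/h", "RATE", "first-order decay rate"),
)


def _toy_entry(assignment: dict, protocol: Protocol,
               output_spec: tuple) -> TimeSeriesResult:
    k = assignment["k_decay"]
    y0 = assignment["y0"]
    if k < 0.0:
        raise ValidationError("toy model requires a non-negative decay rate")
    times = np.arange(0.0, protocol.t_end + 1e-9, protocol.output_interval)
    return TimeSeriesResult(task_id="", times=times,
                            series={"y": y0 * np.exp(-k * times)},
                            metadata={"model": TOY_MODEL_ID})


def build_toy_plugin() -> ModelPlugin:
    return ModelPlugin(model_id=TOY_MODEL_ID,
                       parameters=ParameterSet(_TOY_DEFS),
                       entry_point=_toy_entry)


#: model id -> plugin factory; used by the CLI's stdin/stdout task runner
PLUGIN_REGISTRY = {
    METABOLIC_MODEL_ID: build_metabolic_plugin,
    TOY_MODEL_ID: build_toy_plugin,
}
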