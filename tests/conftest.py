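"""Shared fixtures.

Expensive simulations (steady states, the 28-day escalation arm, the dose-
response battery) are session-scoped so every test reads from one run.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from qspsim.metabolism import (
    MetabolicState, T2DM_OVERRIDES, build_default_parameters, steady_state,
)
from qspsim.model import MetabolicModel
from qspsim.protocols import (
    compute_endpoints, metformin_escalation_protocol, monotherapy_protocol,
)
from qspsim.simulate import simulate

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def healthy_params():
    return build_default_parameters()


@pytest.fixture(scope="session")
def t2dm_params():
    return build_default_parameters().with_overrides(T2DM_OVERRIDES)


@pytest.fixture(scope="session")
def healthy_ss(healthy_params):
    return steady_state(healthy_params)


@pytest.fixture(scope="session")
def t2dm_ss(t2dm_params):
    return steady_state(t2dm_params)


@pytest.fixture()
def t2dm_state(t2dm_ss) -> MetabolicState:
    """A mutable copy of the T2DM fasting state."""
    return MetabolicState.from_vector(t2dm_ss.to_vector())


@pytest.fixture(scope="session")
def escalation_fit():
    """Day-0-calibrated T2DM patient (the reference-arm anchor)."""
    return MetabolicModel.t2dm().fit({"fpg_mM": 10.1, "ogtt_auc_mM_h": 29.9})


@pytest.fixture(scope="session")
def escalation_endpoints(escalation_fit):
    proto = metformin_escalation_protocol()
    return escalation_fit.endpoints(proto, (0, 7, 14, 28))


@pytest.fixture(scope="session")
def dose_response_fpg(t2dm_params, t2dm_ss):
    """Morning fasting glucose on day 14 for metformin 0..1000 mg bid."""
    out = {}
    for dose in (0.0, 250.0, 500.0, 1000.0):
        proto = monotherapy_protocol("metformin", dose, n_days=14,
                                     schedule="bid", ogtt_days=())
        proto.output_interval = 0.25
        res = simulate(t2dm_params, proto, start=t2dm_ss)
        out[dose] = compute_endpoints(res, proto, 14, reference_day=None).FPG
    return out
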