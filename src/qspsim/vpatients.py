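"""Virtual patients: named parameter value sets with phenotype tags.

A virtual patient (VP) is a complete parameterization of the physiology —
stored as a *partial* override map on top of the model's baseline listing,
plus phenotype tags used for selection.  VPs live as human-readable YAML
files (one per patient) in a plain directory store.

Calibration turns clinical anchor values (fasting glucose, OGTT glucose AUC,
fasting insulin) into a VP by adjusting a small set of free parameters —
by default the three canonical type-2-diabetes defects: hepatic insulin
sensitivity, peripheral insulin sensitivity and beta-cell function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import least_squares

from .errors import CalibrationError, ValidationError
from .metabolism import build_default_parameters, steady_state
from .parameters import ParameterSet
from .protocols import (
    Protocol, build_ogtt, compute_endpoints, standard_meals,
)
from .simulate import simulate

#: canonical free parameters for T2DM calibration
DEFAULT_FREE_PARAMS = (
    "hepatic_insulin_sensitivity",
    "peripheral_insulin_sensitivity",
    "beta_cell_function",
)

#: recognized calibration targets and how they are measured
TARGET_NAMES = ("fpg_mM", "ogtt_auc_mM_h", "fpi_pM")


@dataclass(frozen=True)
class VirtualPatient:
    """A named, phenotype-tagged (partial) parameter assignment."""

    id: str
    name: str = ""
    phenotypes: tuple[str, ...] = ()
    overrides: dict[str, float] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValidationError("virtual patient id must be non-empty")
        if not self.phenotypes:
            raise ValidationError("virtual patient needs at least one phenotype tag")

    def resolve(self, base: ParameterSet | None = None) -> ParameterSet:
        """Full parameter listing: baseline with this VP's overrides applied."""
        base = base if base is not None else build_default_parameters()
        return base.with_overrides(self.overrides)


@dataclass(frozen=True)
class ValueSet:
    """A reusable named assignment for one parameter group (e.g. one dose arm)."""

    group: str
    label: str
    values: dict[str, float]
    group_names: tuple[str, ...] = ()   # parameters belonging to the group

    def __post_init__(self):
        if self.group_names:
            stray = sorted(set(self.values) - set(self.group_names))
            if stray:
                raise ValidationError(
                    f"value set {self.label!r}: parameter(s) outside group "
                    f"{self.group!r}: {', '.join(stray)}")


def make_vp(base: ParameterSet, overrides: dict[str, float],
            phenotypes: tuple[str, ...] | list[str],
            id: str = "vp", name: str = "", provenance: str = "") -> VirtualPatient:
    """Validated VP constructor; unknown override names are rejected by name."""
    base.with_overrides(overrides)  # raises ValidationError listing bad names
    return VirtualPatient(id=id, name=name or id, phenotypes=tuple(phenotypes),
                          overrides=dict(overrides), provenance=provenance)


def select_vps(store: list[VirtualPatient], phenotypes, and_logic: bool = False
               ) -> list[VirtualPatient]:
    """Filter a VP store by phenotype tags.

    ``and_logic=True`` keeps VPs carrying *all* requested tags, otherwise any
    tag matches; order is the stable store order either way.
    """
    wanted = set(phenotypes)
    # pure set algebra: an empty request matches everything under AND
    # (vacuous subset) and nothing under OR (empty union)
    if and_logic:
        return [v for v in store if wanted.issubset(v.phenotypes)]
    return [v for v in store if wanted & set(v.phenotypes)]


# -- file store ---------------------------------------------------------------

def save_vp(vp: VirtualPatient, path: str | Path) -> None:
    doc = {
        "id": vp.id, "name": vp.name, "phenotypes": list(vp.phenotypes),
        "overrides": {k: float(v) for k, v in sorted(vp.overrides.items())},
        "provenance": vp.provenance,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_vp(path: str | Path) -> VirtualPatient:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        return VirtualPatient(
            id=doc["id"], name=doc.get("name", doc["id"]),
            phenotypes=tuple(doc.get("phenotypes", ())),
            overrides=dict(doc.get("overrides", {})),
            provenance=doc.get("provenance", ""),
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"malformed VP file {path}: {exc}") from exc


def load_vp_store(directory: str | Path) -> list[VirtualPatient]:
    """All VPs in a directory, in sorted-filename (stable) order."""
    return [load_vp(p) for p in sorted(Path(directory).glob("*.yaml"))]


# -- enrollment screening -----------------------------------------------------

def fasting_glucose_in_range(vp: VirtualPatient, lo: float = 7.0,
                             hi: float = 12.0,
                             base: ParameterSet | None = None) -> bool:
    """Enrollment-style check: fasting steady-state glucose within [lo, hi] mM."""
    fpg = steady_state(vp.resolve(base)).G_plasma
    return lo <= fpg <= hi


# -- calibration --------------------------------------------------------------

def _baseline_ogtt_protocol(auc_window: float, run_in_days: int) -> Protocol:
    return Protocol(
        duration_days=1,
        meals=standard_meals(),
        ogtts=(build_ogtt(75.0, 0, 7.0),),
        outputs=("G_plasma", "I_plasma"),
        output_interval=0.1,
        run_in_days=run_in_days,
        ogtt_auc_window=auc_window,
    )


def measure_observables(params: ParameterSet, targets: dict[str, float],
                        auc_window: float = 2.0,
                        run_in_days: int = 4) -> dict[str, float]:
    """Measure the requested calibration observables for one assignment.

    Fasting-only targets are read from the drug-free fasting steady state.
    When an OGTT AUC target is present, all observables come instead from a
    simulated baseline day (meal run-in, then a morning OGTT), matching how
    day-0 endpoints are measured in study protocols.
    """
    out: dict[str, float] = {}
    unknown = sorted(set(targets) - set(TARGET_NAMES))
    if unknown:
        raise ValidationError(f"unknown calibration target(s): {', '.join(unknown)}")
    if "ogtt_auc_mM_h" in targets:
        proto = _baseline_ogtt_protocol(auc_window, run_in_days)
        ss = steady_state(params)
        res = simulate(params, proto, start=ss)
        ep = compute_endpoints(res, proto, 0, reference_day=None)
        out["fpg_mM"] = ep.FPG
        out["fpi_pM"] = ep.FPI
        out["ogtt_auc_mM_h"] = ep.AUC_glucose
    else:
        ss = steady_state(params)
        out["fpg_mM"] = ss.G_plasma
        out["fpi_pM"] = ss.I_plasma
    return {k: out[k] for k in targets}


def calibrate_vp(
    targets: dict[str, float],
    free_params: tuple[str, ...] = DEFAULT_FREE_PARAMS,
    base: ParameterSet | None = None,
    phenotypes: tuple[str, ...] = ("T2DM",),
    id: str = "vp-calibrated",
    tol: float = 0.02,
    auc_window: float = 2.0,
    run_in_days: int = 4,
    prior_weight: float = 0.01,
    max_nfev: int = 60,
) -> VirtualPatient:
    """Fit ``free_params`` so the model reproduces the target observables.

    Deterministic: fixed start point (the base values), fixed optimizer
    settings.  Raises :class:`CalibrationError` carrying the best residual if
    any target misses by more than ``tol`` (relative).
    """
    base = base if base is not None else build_default_parameters()
    for nm in free_params:
        if nm not in base:
            raise ValidationError(f"unknown free parameter {nm!r}")
    for nm, v in targets.items():
        if not (math.isfinite(v) and v > 0):
            raise ValidationError(f"target {nm!r} must be positive and finite")

    names = list(targets)
    t_vals = np.array([targets[n] for n in names])
    x0 = np.log([base[nm] for nm in free_params])

    def residual(x):
        ps = base.with_overrides(
            {nm: float(np.exp(xi)) for nm, xi in zip(free_params, x)})
        obs = measure_observables(ps, targets, auc_window, run_in_days)
        o = np.array([obs[n] for n in names])
        r = (o - t_vals) / t_vals
        # weak pull toward the starting phenotype keeps the underdetermined
        # directions pinned and the fit reproducible
        return np.concatenate([r, prior_weight * (x - x0)])

    sol = least_squares(residual, x0, method="lm", xtol=1e-10, ftol=1e-10,
                        max_nfev=max_nfev)
    fitted = {nm: float(np.exp(xi)) for nm, xi in zip(free_params, sol.x)}
    obs = measure_observables(base.with_overrides(fitted), targets,
                              auc_window, run_in_days)
    rel = max(abs(obs[n] - targets[n]) / targets[n] for n in names)
    if rel > tol:
        raise CalibrationError(
            f"calibration missed targets (worst relative error {rel:.3%}); "
            f"achieved {obs}", residual=rel)
    prov = ("calibrated to " + ", ".join(f"{k}={targets[k]}" for k in names)
            + f"; worst relative error {rel:.3%}")
    # ship a self-contained VP: any base deviation from the canonical default
    # listing is folded into the overrides alongside the fitted values
    default = build_default_parameters()
    overrides = {nm: base[nm] for nm in base.names() if base[nm] != default[nm]}
    overrides.update(fitted)
    return VirtualPatient(id=id, name=id, phenotypes=tuple(phenotypes),
                          overrides=overrides, provenance=prov)
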