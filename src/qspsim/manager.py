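"""Model-agnostic simulation management.

The manager never looks inside a model: a *plugin* is just a model id, a
full input-parameter listing, and an entry point that maps (complete
parameter assignment, protocol, output spec) to a time-series result.  A
complete assignment plus a protocol *is* one simulation task; tasks are
expanded from virtual-patient x therapy selections, serialized to plain-text
documents, executed in parallel with per-task failure isolation, and
persisted to a manifest-indexed directory of CSV files.
"""

from __future__ import annotations

import hashlib
import json
import traceback
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Callable

import yaml

from .errors import (
    ConfigurationError, IntegrityError, SerializationError, ValidationError,
)
from .parameters import ParameterSet
from .protocols import Protocol, protocol_from_dict, protocol_to_dict
from .results import TimeSeriesResult
from .units import convert_units  # re-exported: category-scoped conversions
from .vpatients import ValueSet, VirtualPatient

__all__ = [
    "ModelPlugin", "SimulationTask", "TaskFailure", "SchemaControl",
    "ExposedParameterSchema", "expand_tasks", "serialize_task", "parse_task",
    "run_batch", "validate_schema", "store_results", "load_results",
    "convert_units",
]


@dataclass
class ModelPlugin:
    """A self-contained simulator: behaviour depends only on its inputs."""

    model_id: str
    parameters: ParameterSet
    entry_point: Callable[[dict, Protocol, tuple], TimeSeriesResult]

    def run(self, task: "SimulationTask") -> TimeSeriesResult:
        if task.model_id != self.model_id:
            raise ConfigurationError(
                f"task targets model {task.model_id!r}, plugin is {self.model_id!r}")
        result = self.entry_point(task.assignment, task.protocol,
                                  task.output_spec)
        result.task_id = task.task_id
        return result


@dataclass(frozen=True)
class SimulationTask:
    """One fully specified run: complete assignment + protocol + outputs."""

    model_id: str
    assignment: dict[str, float]
    protocol: Protocol
    output_spec: tuple[str, ...]
    vp_id: str = ""
    therapy_labels: tuple[str, ...] = ()

    @property
    def task_id(self) -> str:
        """Deterministic content hash of the serialized task document."""
        doc = serialize_task(self, _for_hash=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class TaskFailure:
    """Captured per-task error; a failing task never aborts its batch."""

    task_id: str
    error: str


# -- expansion ----------------------------------------------------------------

def expand_tasks(
    vps: list[VirtualPatient],
    therapy_options: list[list[ValueSet]],
    mode: str,
    protocol: Protocol,
    output_spec: tuple[str, ...],
    base: ParameterSet,
    model_id: str = "metabolic",
) -> list[SimulationTask]:
    """Fan a VP x therapy selection out into independent tasks.

    ``crossed`` produces one task per VP per Cartesian combination of the
    option lists (|vps| x prod |options_i|); ``combination`` applies every
    selected option simultaneously to each VP (|vps| tasks).  Ordering is
    deterministic: VP-major, then option-lexicographic.
    """
    if mode not in ("crossed", "combination"):
        raise ValidationError(f"unknown expansion mode {mode!r}")
    for opts in therapy_options:
        if not opts:
            raise ValidationError("empty therapy option list")

    if mode == "crossed":
        combos = list(product(*therapy_options)) if therapy_options else [()]
    else:
        combo = tuple(o for opts in therapy_options for o in opts)
        seen: dict[str, str] = {}
        for vs in combo:
            for name in vs.values:
                if name in seen:
                    raise ConfigurationError(
                        f"combination conflict: parameter {name!r} set by both "
                        f"{seen[name]!r} and {vs.label!r}")
                seen[name] = vs.label
        combos = [combo]

    tasks: list[SimulationTask] = []
    for vp in vps:
        resolved = vp.resolve(base)
        for combo in combos:
            ps = resolved
            for vs in combo:
                ps = ps.with_overrides(vs.values)
            tasks.append(SimulationTask(
                model_id=model_id,
                assignment=ps.as_dict(),
                protocol=protocol,
                output_spec=tuple(output_spec),
                vp_id=vp.id,
                therapy_labels=tuple(vs.label for vs in combo),
            ))
    return tasks


# -- plain-text task documents -------------------------------------------------

_DOC_HEADER = "# simulation task v1"


def serialize_task(task: SimulationTask, plugin: ModelPlugin | None = None,
                   _for_hash: bool = False) -> str:
    """Plain-text document: one ``name<TAB>value<TAB>unit`` line per parameter
    plus protocol and output blocks.  Round-trips bit-exactly through
    :func:`parse_task`.

    When a plugin is given, the assignment is checked for completeness
    against its listing and units are taken from the definitions.
    """
    units = {}
    if plugin is not None:
        missing = sorted(set(plugin.parameters.names()) - set(task.assignment))
        if missing:
            raise SerializationError(
                f"incomplete assignment, missing: {', '.join(missing)}")
        units = {n: plugin.parameters.definition(n).unit
                 for n in plugin.parameters.names()}
    lines = [_DOC_HEADER,
             "[model]", f"id\t{task.model_id}",
             "[vp]", f"id\t{task.vp_id}",
             "[therapies]"]
    lines += [f"label\t{lbl}" for lbl in task.therapy_labels]
    lines.append("[parameters]")
    for name in sorted(task.assignment):
        unit = units.get(name, "")
        lines.append(f"{name}\t{task.assignment[name]!r}\t{unit}")
    lines.append("[protocol]")
    lines.append(yaml.safe_dump(protocol_to_dict(task.protocol),
                                sort_keys=True).rstrip())
    lines.append("[outputs]")
    lines += list(task.output_spec)
    if not _for_hash:
        lines.append("[end]")
    return "\n".join(lines) + "\n"


def parse_task(doc: str) -> SimulationTask:
    sections: dict[str, list[str]] = {}
    current = None
    for line in doc.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            sections[current] = []
            continue
        if current is None:
            raise SerializationError(f"content outside any section: {line!r}")
        sections[current].append(line)
    for required in ("model", "parameters", "protocol", "outputs"):
        if required not in sections:
            raise SerializationError(f"task document lacks [{required}] section")

    def kv(lines):
        out = {}
        for ln in lines:
            k, _, v = ln.partition("\t")
            out[k] = v
        return out

    model_id = kv(sections["model"]).get("id", "")
    vp_id = kv(sections.get("vp", [])).get("id", "")
    labels = tuple(ln.partition("\t")[2] for ln in sections.get("therapies", []))
    assignment: dict[str, float] = {}
    for ln in sections["parameters"]:
        parts = ln.split("\t")
        if len(parts) < 2:
            raise SerializationError(f"malformed parameter line {ln!r}")
        assignment[parts[0]] = float(parts[1])
    proto = protocol_from_dict(yaml.safe_load("\n".join(sections["protocol"])))
    outputs = tuple(sections["outputs"])
    return SimulationTask(model_id=model_id, assignment=assignment,
                          protocol=proto, output_spec=outputs, vp_id=vp_id,
                          therapy_labels=labels)


# -- execution ----------------------------------------------------------------

def _run_one(args):
    plugin, task = args
    try:
        return plugin.run(task)
    except Exception as exc:  # noqa: BLE001 - failures isolate per task
        return TaskFailure(task_id=task.task_id,
                           error=f"{type(exc).__name__}: {exc}\n"
                                 + traceback.format_exc(limit=3))


def run_batch(tasks: list[SimulationTask], plugin: ModelPlugin,
              workers: int = 1) -> list[TimeSeriesResult | TaskFailure]:
    """Execute tasks, returning results in task order.

    The worker count only affects wall time, never values: each task is
    independent and deterministic.  Exceptions become :class:`TaskFailure`
    records and the batch continues.
    """
    if workers < 1:
        raise ValidationError("workers must be >= 1")
    if not tasks:
        return []
    args = [(plugin, t) for t in tasks]
    if workers == 1 or len(tasks) == 1:
        return [_run_one(a) for a in args]
    with ProcessPoolExecutor(max_workers=workers) as pool:
        return list(pool.map(_run_one, args))


# -- exposed-parameter schema --------------------------------------------------

_CONTROL_KINDS = ("checkbox", "text", "dropdown")


@dataclass(frozen=True)
class SchemaControl:
    section: str
    parameter: str
    label: str
    kind: str           # checkbox | text | dropdown
    category: str       # DOSE | TIME | ... (unit-conversion scope)
    row: int
    col: int


@dataclass
class ExposedParameterSchema:
    """Declarative description of which parameters a front-end exposes and
    how they are laid out (section, grid row/column, control kind)."""

    controls: list[SchemaControl] = field(default_factory=list)

    def keyword_filter(self, plugin: ModelPlugin, keyword: str) -> list[str]:
        """All plugin parameters whose name contains ``keyword``."""
        return plugin.parameters.filter_names(keyword)


def validate_schema(schema: ExposedParameterSchema,
                    plugin: ModelPlugin) -> list[str]:
    """Report problems; an empty list means the schema is consistent."""
    report: list[str] = []
    cells: dict[tuple[str, int, int], str] = {}
    for c in schema.controls:
        if c.parameter not in plugin.parameters:
            report.append(f"unknown parameter {c.parameter!r} in section {c.section!r}")
        else:
            defn = plugin.parameters.definition(c.parameter)
            if c.category != defn.category:
                report.append(
                    f"category mismatch for {c.parameter!r}: schema says "
                    f"{c.category!r}, model says {defn.category!r}")
        if c.kind not in _CONTROL_KINDS:
            report.append(f"unknown control kind {c.kind!r} for {c.parameter!r}")
        key = (c.section, c.row, c.col)
        if key in cells:
            report.append(
                f"duplicate grid cell {key} used by {cells[key]!r} and "
                f"{c.parameter!r}")
        cells[key] = c.parameter
    return report


# -- persistence ---------------------------------------------------------------

def store_results(results: list[TimeSeriesResult | TaskFailure],
                  directory: str | Path) -> Path:
    """Write one CSV per result plus a checksummed manifest; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, r in enumerate(results):
        if isinstance(r, TaskFailure):
            entries.append({"task_id": r.task_id, "status": "failed",
                            "error": r.error.splitlines()[0]})
            continue
        fname = f"{r.task_id or f'result{i:04d}'}.csv"
        text = r.to_csv()
        (directory / fname).write_text(text)
        entries.append({
            "task_id": r.task_id, "status": "ok", "file": fname,
            "sha256": hashlib.sha256(text.encode()).hexdigest(),
        })
    manifest = directory / "manifest.json"
    manifest.write_text(json.dumps({"version": 1, "results": entries}, indent=1))
    return manifest


def load_results(manifest_path: str | Path) -> list[TimeSeriesResult | TaskFailure]:
    """Load a stored batch; checksum mismatches raise naming the task."""
    manifest_path = Path(manifest_path)
    directory = manifest_path.parent
    doc = json.loads(manifest_path.read_text())
    out: list[TimeSeriesResult | TaskFailure] = []
    for e in doc["results"]:
        if e.get("status") == "failed":
            out.append(TaskFailure(task_id=e["task_id"], error=e.get("error", "")))
            continue
        path = directory / e["file"]
        if not path.exists():
            raise IntegrityError(f"result file missing for task {e['task_id']}")
        text = path.read_text()
        digest = hashlib.sha256(text.encode()).hexdigest()
        if digest != e["sha256"]:
            raise IntegrityError(
                f"checksum mismatch for task {e['task_id']} ({e['file']})")
        out.append(TimeSeriesResult.from_csv(text))
    return out


def run_task_subprocess(task: SimulationTask, command: list[str],
                        timeout: float | None = None) -> TimeSeriesResult:
    """Drive an external simulator process with the plain-text contract.

    The serialized task document is written to the child's stdin and a
    result CSV is read from its stdout — the same "executable + input text
    file defines the simulation" contract the in-process plugins follow, so
    an external binary can stand in for a registered plugin.
    """
    import subprocess

    doc = serialize_task(task)
    proc = subprocess.run(command, input=doc.encode(), capture_output=True,
                          timeout=timeout)
    if proc.returncode != 0:
        raise ConfigurationError(
            f"external simulator failed (exit {proc.returncode}): "
            f"{proc.stderr.decode(errors='replace')[:500]}")
    result = TimeSeriesResult.from_csv(proc.stdout.decode())
    result.task_id = task.task_id
    return result
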