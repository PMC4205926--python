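"""Model parameter listings.

The full parameter listing *is* a model's input interface: every constant of
the physiology and of the drug sub-models appears by name, with a unit and a
category, and a complete assignment (plus a protocol) fully defines one
simulation.  The listing round-trips through the plain-text format
``name<TAB>value<TAB>unit``, one line per parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

from .errors import SerializationError, ValidationError


@dataclass(frozen=True)
class ParameterDef:
    """Definition of one named model parameter."""

    name: str
    default: float
    unit: str = "dimensionless"
    category: str = "RATE"
    doc: str = ""


class ParameterSet:
    """An ordered, named map parameter -> value with unit/category metadata.

    The ordering is fixed at construction and shared by every value array the
    set produces, so numerical kernels can address parameters by integer index.
    """

    def __init__(self, defs: Iterable[ParameterDef]):
        self._defs: list[ParameterDef] = list(defs)
        self._index: dict[str, int] = {}
        for i, d in enumerate(self._defs):
            if d.name in self._index:
                raise ValidationError(f"duplicate parameter name {d.name!r}")
            if not math.isfinite(d.default):
                raise ValidationError(f"parameter {d.name!r} has non-finite default")
            self._index[d.name] = i
        self._values = np.array([d.default for d in self._defs], dtype=float)

    # -- mapping-ish surface -------------------------------------------------
    def __len__(self) -> int:
        return len(self._defs)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __iter__(self) -> Iterator[str]:
        return iter(self._index)

    def names(self) -> tuple[str, ...]:
        return tuple(self._index)

    def __getitem__(self, name: str) -> float:
        return float(self._values[self._index[name]])

    def __setitem__(self, name: str, value: float) -> None:
        if name not in self._index:
            raise ValidationError(f"unknown parameter name {name!r}")
        if not math.isfinite(value):
            raise ValidationError(f"non-finite value for parameter {name!r}")
        self._values[self._index[name]] = value

    def definition(self, name: str) -> ParameterDef:
        return self._defs[self._index[name]]

    def index(self, name: str) -> int:
        return self._index[name]

    def values(self) -> np.ndarray:
        """Copy of the value vector, in definition order."""
        return self._values.copy()

    def as_dict(self) -> dict[str, float]:
        return {d.name: float(v) for d, v in zip(self._defs, self._values)}

    def copy(self) -> "ParameterSet":
        new = ParameterSet(self._defs)
        new._values = self._values.copy()
        return new

    def with_overrides(self, overrides: Mapping[str, float]) -> "ParameterSet":
        """New set with ``overrides`` applied; unknown names are rejected."""
        unknown = sorted(set(overrides) - set(self._index))
        if unknown:
            raise ValidationError(f"unknown parameter name(s): {', '.join(unknown)}")
        new = self.copy()
        for k, v in overrides.items():
            new[k] = v
        return new

    def filter_names(self, keyword: str) -> list[str]:
        """All parameter names containing ``keyword`` as a substring."""
        return [n for n in self._index if keyword in n]

    # -- plain-text interface ------------------------------------------------
    def to_text(self) -> str:
        """Full listing, one ``name<TAB>value<TAB>unit`` line per parameter."""
        lines = [
            f"{d.name}\t{v!r}\t{d.unit}"
            for d, v in zip(self._defs, self._values)
        ]
        return "\n".join(lines) + "\n"

    def update_from_text(self, text: str) -> "ParameterSet":
        """New set with values read from a full ``to_text`` listing.

        Every parameter of the set must appear exactly once; values are parsed
        with full precision so the round trip is bit-exact.
        """
        values: dict[str, float] = {}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise SerializationError(f"malformed parameter line {lineno}: {line!r}")
            name, value = parts[0], parts[1]
            if name not in self._index:
                raise SerializationError(f"unknown parameter name {name!r} on line {lineno}")
            if name in values:
                raise SerializationError(f"duplicate parameter {name!r} on line {lineno}")
            values[name] = float(value)
        missing = sorted(set(self._index) - set(values))
        if missing:
            raise SerializationError(f"missing parameter(s): {', '.join(missing)}")
        new = self.copy()
        for k, v in values.items():
            new[k] = v
        return new


@dataclass
class ParameterGroup:
    """A named subset of a parameter listing, as surfaced by a configurable UI."""

    group: str
    names: list[str] = field(default_factory=list)
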