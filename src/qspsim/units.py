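"""Unit registry and category-scoped conversion.

Exposed parameters carry a *category* (DOSE, TIME, ...) that scopes which unit
conversions are legal for them, mirroring how simulation front-ends convert a
dose typed in grams into the milligrams the model expects.  Conversions are
exact multiplicative factors, so round trips are lossless.
"""

from __future__ import annotations

from .errors import UnitConversionError

#: canonical unit and conversion factors *to* the canonical unit, per category
_CATEGORY_UNITS: dict[str, dict[str, float]] = {
    "DOSE": {"mg": 1.0, "g": 1e3, "ug": 1e-3, "kg": 1e6},
    "TIME": {"h": 1.0, "min": 1.0 / 60.0, "s": 1.0 / 3600.0, "day": 24.0},
    "MASS": {"g": 1.0, "mg": 1e-3, "kg": 1e3},
    "CONC": {"mM": 1.0, "uM": 1e-3, "nM": 1e-6},
    "HORMONE": {"pM": 1.0, "nM": 1e3},
    "VOLUME": {"L": 1.0, "mL": 1e-3},
    "ENERGY": {"kcal": 1.0, "kJ": 1.0 / 4.184},
}

CATEGORIES = tuple(_CATEGORY_UNITS)


def registered_units(category: str) -> tuple[str, ...]:
    """Units registered for ``category`` (first entry is canonical)."""
    try:
        return tuple(_CATEGORY_UNITS[category])
    except KeyError as exc:
        raise UnitConversionError(f"unknown unit category {category!r}") from exc


def convert_units(value: float, category: str, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between two units registered under ``category``.

    Raises
    ------
    UnitConversionError
        If the category is unknown or either unit is not registered for it.
    """
    table = _CATEGORY_UNITS.get(category)
    if table is None:
        raise UnitConversionError(f"unknown unit category {category!r}")
    try:
        f_from = table[from_unit]
        f_to = table[to_unit]
    except KeyError as exc:
        raise UnitConversionError(
            f"no conversion {from_unit!r} -> {to_unit!r} registered for category {category!r}"
        ) from exc
    if from_unit == to_unit:
        return value
    return value * (f_from / f_to)
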