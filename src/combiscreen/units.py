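"""Concentration-unit handling.

Screens in this domain routinely mix mg/mL and µg/mL across drugs (a
cyclophosphamide grid is dosed in mg/mL while doxorubicin and vincristine are
in µg/mL), so dose comparisons within a drug normalize to a canonical unit
first. Conversions are only defined within a dimension (mass concentration or
molar concentration); crossing dimensions raises :class:`~combiscreen.errors.UnitError`
because it would need a molar mass the table does not carry.

CI and DRI are dose ratios *within* a drug, so no cross-drug conversion is
ever performed.
"""

from __future__ import annotations

from .errors import UnitError

# factors to the canonical unit of each dimension
_MASS_CANON = "mg/mL"
_MASS_FACTORS = {
    "g/mL": 1e3,
    "mg/mL": 1.0,
    "ug/mL": 1e-3,
    "µg/mL": 1e-3,
    "μg/mL": 1e-3,
    "ng/mL": 1e-6,
    "pg/mL": 1e-9,
    "g/L": 1.0,
    "mg/L": 1e-3,
    "ug/L": 1e-6,
    "µg/L": 1e-6,
    "ng/L": 1e-9,
}

_MOLAR_CANON = "M"
_MOLAR_FACTORS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "μM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}


def _dimension(unit: str) -> tuple[str, float] | None:
    """Return (canonical unit, factor) for a known unit, else None."""
    if unit in _MASS_FACTORS:
        return _MASS_CANON, _MASS_FACTORS[unit]
    if unit in _MOLAR_FACTORS:
        return _MOLAR_CANON, _MOLAR_FACTORS[unit]
    return None


def canonical_dose(value: float, unit: str) -> tuple[float, str]:
    """Express a dose in the canonical unit of its dimension.

    Unknown units are passed through unchanged (they are their own canonical
    unit), so tables with exotic but self-consistent units still work.
    """
    dim = _dimension(unit)
    if dim is None:
        return value, unit
    canon, factor = dim
    return value * factor, canon


def convert_dose(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a dose between compatible units.

    Raises
    ------
    UnitError
        If the units belong to different dimensions, or one is unknown and
        they are not string-identical.
    """
    if from_unit == to_unit:
        return value
    src, dst = _dimension(from_unit), _dimension(to_unit)
    if src is None or dst is None or src[0] != dst[0]:
        raise UnitError(f"cannot convert {from_unit!r} to {to_unit!r}")
    return value * src[1] / dst[1]


def compatible(unit_a: str, unit_b: str) -> bool:
    """True if a dose in ``unit_a`` can be converted to ``unit_b``."""
    if unit_a == unit_b:
        return True
    a, b = _dimension(unit_a), _dimension(unit_b)
    return a is not None and b is not None and a[0] == b[0]
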