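"""Unit handling for the donor cohort data model.

Canonical internal units match the clinical convention of the source
laboratory: plasma creatinine in µmol/l, plasma cystatin C in mg/l, GFR in
ml/min per 1.73 m² of body surface area, 24-h urinary creatinine excretion
in mmol/24 h.  The CKD-EPI equations are defined on mg/dl creatinine, so a
conversion layer is needed at the equation boundary.
"""

from __future__ import annotations

# 1 mg/dl creatinine = 88.4 µmol/l (molar mass 113.12 g/mol)
CREATININE_UMOL_PER_MGDL = 88.4

#: aliases accepted on input, mapped to canonical spellings
_ALIASES = {
    "umol/l": "umol/l",
    "µmol/l": "umol/l",
    "μmol/l": "umol/l",
    "mg/dl": "mg/dl",
    "mg/l": "mg/l",
    "mmol": "mmol",
    "umol": "umol",
    "µmol": "umol",
    "mmol/24h": "mmol",
    "umol/24h": "umol",
}

# (from, to) -> multiplicative factor
_FACTORS = {
    ("umol/l", "mg/dl"): 1.0 / CREATININE_UMOL_PER_MGDL,
    ("mg/dl", "umol/l"): CREATININE_UMOL_PER_MGDL,
    ("mmol", "umol"): 1000.0,
    ("umol", "mmol"): 1e-3,
}


class UnitError(ValueError):
    """Raised for an unknown unit string or an unsupported conversion pair."""


def normalize_unit(unit: str) -> str:
    key = unit.strip().lower()
    try:
        return _ALIASES[key]
    except KeyError:
        raise UnitError(f"unknown unit string: {unit!r}") from None


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between supported clinical units.

    Supported pairs: creatinine µmol/l ↔ mg/dl, mmol ↔ µmol, and the
    identity for any recognized unit (e.g. cystatin C mg/l passthrough).
    Conversions are exact multiplicative factors, so round-trips are
    identities to floating-point precision.
    """
    f, t = normalize_unit(from_unit), normalize_unit(to_unit)
    if f == t:
        return value
    try:
        return value * _FACTORS[(f, t)]
    except KeyError:
        raise UnitError(f"unsupported unit conversion: {from_unit!r} -> {to_unit!r}") from None
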