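"""The eight GFR estimating equations evaluated against measured GFR.

Two families are implemented:

* **CKD-EPI** piecewise power-law equations — 2009 (creatinine), 2012
  (cystatin C), 2012 (combined), 2021 race-free (creatinine) and 2021
  race-free (combined).  Each marker m contributes
  ``min(m/κ, 1)^α_low · max(m/κ, 1)^α_high`` with a sex-specific threshold
  κ, multiplied by an age-decay term and a sex multiplier.  The cohort
  these equations are applied to is all-white and no race correction is
  used anywhere; no race variable exists in the data model.

* **EKFC** rescaled-biomarker equations — the marker is divided by a
  population normalization value Q (the median in healthy persons of that
  sex/age), and ``107.3 · (m/Q)^exp`` with a steeper exponent above
  m/Q = 1, times ``0.990^(age−40)`` beyond age 40.  The combined EKFC
  estimate is the arithmetic mean of the two single-marker estimates.

Coefficients live in ``data/equations.yaml`` so they can be audited
against the primary publications.  Creatinine enters CKD-EPI in mg/dl
(converted internally from the canonical µmol/l); EKFC creatinine Q values
are in µmol/l.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from functools import lru_cache

import pandas as pd
import yaml

from .cohort import FEMALE, MALE, CohortTable
from .units import convert_units

log = logging.getLogger(__name__)

CKDEPI_EQUATIONS = (
    "ckdepi_2009_creat", "ckdepi_2012_cys", "ckdepi_2012_comb",
    "ckdepi_2021_creat", "ckdepi_2021_comb",
)
EKFC_EQUATIONS = ("ekfc_creat", "ekfc_cys", "ekfc_comb")
ALL_EQUATIONS = CKDEPI_EQUATIONS + EKFC_EQUATIONS

#: equations whose marker set includes cystatin C
CYSTATIN_EQUATIONS = ("ckdepi_2012_cys", "ckdepi_2012_comb", "ckdepi_2021_comb",
                      "ekfc_cys", "ekfc_comb")
#: equations based on creatinine only
CREATININE_ONLY_EQUATIONS = ("ckdepi_2009_creat", "ckdepi_2021_creat", "ekfc_creat")


class EquationError(ValueError):
    """Missing or non-positive marker, unknown equation name."""


@lru_cache(maxsize=1)
def equation_specs() -> dict:
    """Load the coefficient tables shipped with the package."""
    ref = importlib.resources.files("donorgfr").joinpath("data/equations.yaml")
    return yaml.safe_load(ref.read_text(encoding="utf-8"))


def equation_markers(name: str) -> tuple[str, ...]:
    try:
        return tuple(equation_specs()[name]["markers"])
    except KeyError:
        raise EquationError(f"unknown equation: {name!r}") from None


def _check_marker(name: str, marker: str, value: float | None) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise EquationError(f"{name}: required marker {marker!r} is missing")
    if not value > 0:
        raise EquationError(f"{name}: marker {marker!r} must be positive, got {value}")
    return float(value)


def _check_sex_age(sex: str, age: float) -> None:
    if sex not in (FEMALE, MALE):
        raise EquationError(f"sex must be {FEMALE!r} or {MALE!r}, got {sex!r}")
    if not age > 0:
        raise EquationError(f"age must be positive, got {age}")


def evaluate_ckdepi(name: str, sex: str, age: float,
                    creatinine: float | None = None,
                    cystatin_c: float | None = None) -> float:
    """Evaluate a CKD-EPI equation.

    Parameters are in canonical cohort units (creatinine µmol/l, cystatin C
    mg/l); the creatinine term converts to mg/dl internally.  Returns eGFR
    in ml/min/1.73 m².
    """
    if name not in CKDEPI_EQUATIONS:
        raise EquationError(f"not a CKD-EPI equation: {name!r}")
    _check_sex_age(sex, age)
    spec = equation_specs()[name]
    value = spec["intercept"] * spec["age_base"] ** age
    if sex == FEMALE:
        value *= spec["female_multiplier"]
    available = {"creatinine": creatinine, "cystatin_c": cystatin_c}
    for marker in spec["markers"]:
        m = _check_marker(name, marker, available[marker])
        if marker == "creatinine":
            m = convert_units(m, "umol/l", "mg/dl")
        coeffs = spec[marker]
        kappa = coeffs["kappa"][sex]
        ratio = m / kappa
        value *= min(ratio, 1.0) ** coeffs["alpha_low"][sex]
        value *= max(ratio, 1.0) ** coeffs["alpha_high"][sex]
    return value


def ekfc_q(name: str, sex: str, age: float) -> float:
    """Population rescaling value Q for a single-marker EKFC equation.

    Creatinine: sex-specific adult value (62/80 µmol/l) from age 25, a
    published age polynomial below.  Cystatin C: sex-free 0.83 mg/l,
    increasing 0.005 mg/l per year above age 50.
    """
    spec = equation_specs()[name]
    if name == "ekfc_creat":
        if age >= 25:
            return float(spec["q_adult"][sex])
        if age < 2:
            raise EquationError(f"{name}: no Q defined below age 2 (age={age})")
        p = spec["q_poly"][sex]
        return math.exp(p["c0"] + p["c1"] * age + p["clog"] * math.log(age)
                        + p["c2"] * age ** 2 + p["c3"] * age ** 3)
    if name == "ekfc_cys":
        return float(spec["q_base"] + spec["q_age_slope"] * max(age - 50.0, 0.0))
    raise EquationError(f"no Q for equation {name!r}")


def evaluate_ekfc(name: str, sex: str, age: float, marker: float) -> float:
    """Evaluate a single-marker EKFC equation (marker in canonical units)."""
    if name not in ("ekfc_creat", "ekfc_cys"):
        raise EquationError(f"not a single-marker EKFC equation: {name!r}")
    _check_sex_age(sex, age)
    spec = equation_specs()[name]
    m = _check_marker(name, spec["markers"][0], marker)
    ratio = m / ekfc_q(name, sex, age)
    exp = spec["exponent_low"] if ratio < 1.0 else spec["exponent_high"]
    value = spec["intercept"] * ratio ** exp
    if age > spec["age_onset"]:
        value *= spec["age_base"] ** (age - spec["age_onset"])
    return value


def evaluate_ekfc_combined(sex: str, age: float, creatinine: float,
                           cystatin_c: float) -> float:
    """Arithmetic mean of the creatinine and cystatin C EKFC estimates."""
    _check_marker("ekfc_comb", "creatinine", creatinine)
    _check_marker("ekfc_comb", "cystatin_c", cystatin_c)
    return 0.5 * (evaluate_ekfc("ekfc_creat", sex, age, creatinine)
                  + evaluate_ekfc("ekfc_cys", sex, age, cystatin_c))


def evaluate_equation(name: str, sex: str, age: float,
                      creatinine: float | None = None,
                      cystatin_c: float | None = None) -> float:
    """Dispatch to the right family for any of the eight equation names."""
    if name in CKDEPI_EQUATIONS:
        return evaluate_ckdepi(name, sex, age, creatinine, cystatin_c)
    if name == "ekfc_creat":
        return evaluate_ekfc(name, sex, age, _check_marker(name, "creatinine", creatinine))
    if name == "ekfc_cys":
        return evaluate_ekfc(name, sex, age, _check_marker(name, "cystatin_c", cystatin_c))
    if name == "ekfc_comb":
        _check_sex_age(sex, age)
        return evaluate_ekfc_combined(sex, age, creatinine, cystatin_c)
    raise EquationError(f"unknown equation: {name!r}")


def apply_all_equations(cohort: CohortTable) -> pd.DataFrame:
    """Evaluate every equation for every donor.

    Returns a long table ``(donor_id, equation, egfr)`` with one row per
    donor per evaluable equation.  Equations that need a marker the donor
    lacks are skipped for that donor and logged, never raised.
    """
    if len(cohort) == 0:
        return pd.DataFrame(columns=["donor_id", "equation", "egfr"])
    attr = {"creatinine": "plasma_creatinine", "cystatin_c": "plasma_cystatin_c"}
    rows = []
    for rec in cohort.records():
        for name in ALL_EQUATIONS:
            missing = [m for m in equation_markers(name) if getattr(rec, attr[m]) is None]
            if missing:
                log.info("donor %s: skipping %s (missing %s)", rec.donor_id, name, missing)
                continue
            egfr = evaluate_equation(name, rec.sex, rec.age,
                                     creatinine=rec.plasma_creatinine,
                                     cystatin_c=rec.plasma_cystatin_c)
            rows.append((rec.donor_id, name, egfr))
    return pd.DataFrame(rows, columns=["donor_id", "equation", "egfr"])
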