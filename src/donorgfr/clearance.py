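"""Measured GFR from dual-tracer constant-infusion clearance data.

The gold-standard GFR measurement infuses ¹²⁵I-iothalamate (filtration
marker) together with ¹³¹I-hippurate.  Per steady-state clearance period,

* urinary clearance = U·V / P  (urinary excretion rate over plasma level),
* plasma clearance  = I·V / P  (infusion rate over plasma level).

Incomplete urine collection biases U·V downward for both tracers equally,
so the urinary iothalamate clearance is corrected by the ratio of plasma
to urinary hippurate clearance.  The corrected clearance is indexed to the
conventional 1.73 m² body surface area using the DuBois–DuBois formula.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

BSA_REFERENCE = 1.73  # m²


class ClearanceError(ValueError):
    pass


@dataclasses.dataclass
class TracerMeasurement:
    """Quantities for one tracer in one clearance period.

    ``urinary_excretion_rate`` (U·V) and ``infusion_rate`` (I·V) share an
    activity-per-minute unit; ``plasma_concentration`` (P) is activity/ml.
    The activity unit cancels in every clearance, so only internal
    consistency matters.
    """

    tracer: str  # "iothalamate" | "hippurate"
    urinary_excretion_rate: float
    plasma_concentration: float
    infusion_rate: float

    def __post_init__(self) -> None:
        if self.tracer not in ("iothalamate", "hippurate"):
            raise ClearanceError(f"unknown tracer {self.tracer!r}")
        for f in ("urinary_excretion_rate", "plasma_concentration", "infusion_rate"):
            if not getattr(self, f) > 0:
                raise ClearanceError(f"{f} must be positive")


@dataclasses.dataclass
class MgfrResult:
    clearance_raw: float        # ml/min, uncorrected urinary iothalamate
    clearance_corrected: float  # ml/min
    bsa: float                  # m²
    mgfr_indexed: float         # ml/min/1.73 m²


def tracer_clearance(numerator_rate: float, plasma: float) -> float:
    """Clearance in ml/min: an activity rate (U·V or I·V) over plasma level P."""
    if not plasma > 0:
        raise ClearanceError(f"plasma concentration must be positive, got {plasma}")
    if numerator_rate < 0:
        raise ClearanceError("activity rate cannot be negative")
    return numerator_rate / plasma


def correct_iothalamate(urinary_cl_ioth: float, plasma_cl_hip: float,
                        urinary_cl_hip: float) -> float:
    """Correct urinary iothalamate clearance for urine collection errors.

    Multiplies by plasma/urinary hippurate clearance; equals the input when
    the two hippurate clearances agree (complete collection).
    """
    if not urinary_cl_hip > 0:
        raise ClearanceError("urinary hippurate clearance must be positive")
    if not (urinary_cl_ioth > 0 and plasma_cl_hip > 0):
        raise ClearanceError("clearances must be positive")
    return urinary_cl_ioth * (plasma_cl_hip / urinary_cl_hip)


def bsa_dubois(height: float, weight: float) -> float:
    """DuBois–DuBois body surface area (m²) from height (cm) and weight (kg)."""
    if not (height > 0 and weight > 0):
        raise ClearanceError("height and weight must be positive")
    return 0.007184 * height ** 0.725 * weight ** 0.425


def index_to_bsa(clearance: float, bsa: float) -> float:
    """Index an absolute clearance (ml/min) to 1.73 m² BSA."""
    if not bsa > 0:
        raise ClearanceError(f"BSA must be positive, got {bsa}")
    return clearance * BSA_REFERENCE / bsa


def deindex_from_bsa(mgfr_indexed: float, bsa: float) -> float:
    """Inverse of :func:`index_to_bsa`: back to absolute ml/min."""
    if not bsa > 0:
        raise ClearanceError(f"BSA must be positive, got {bsa}")
    return mgfr_indexed * bsa / BSA_REFERENCE


def mgfr_from_periods(periods: Sequence[tuple[TracerMeasurement, TracerMeasurement]],
                      height: float, weight: float) -> MgfrResult:
    """Measured GFR from one or more (iothalamate, hippurate) period pairs.

    Each period's urinary iothalamate clearance is corrected with that
    period's hippurate ratio; periods are then averaged (arithmetic mean)
    and the result indexed to 1.73 m².
    """
    if not periods:
        raise ClearanceError("at least one clearance period required")
    raw, corrected = [], []
    for ioth, hip in periods:
        if ioth.tracer != "iothalamate" or hip.tracer != "hippurate":
            raise ClearanceError("each period needs (iothalamate, hippurate) in that order")
        cl_ioth = tracer_clearance(ioth.urinary_excretion_rate, ioth.plasma_concentration)
        cl_hip_ur = tracer_clearance(hip.urinary_excretion_rate, hip.plasma_concentration)
        cl_hip_pl = tracer_clearance(hip.infusion_rate, hip.plasma_concentration)
        raw.append(cl_ioth)
        corrected.append(correct_iothalamate(cl_ioth, cl_hip_pl, cl_hip_ur))
    bsa = bsa_dubois(height, weight)
    mean_corr = float(np.mean(corrected))
    return MgfrResult(clearance_raw=float(np.mean(raw)),
                      clearance_corrected=mean_corr,
                      bsa=bsa,
                      mgfr_indexed=index_to_bsa(mean_corr, bsa))


def mgfr_from_csv(df: pd.DataFrame, anthropometrics: pd.DataFrame) -> pd.DataFrame:
    """Per-donor mGFR from a long table of per-period tracer measurements.

    ``df`` columns: donor_id, period, tracer, urinary_excretion_rate,
    plasma_concentration, infusion_rate.  ``anthropometrics`` columns:
    donor_id, height, weight.  Returns donor_id → mgfr_pre (indexed).
    """
    anth = anthropometrics.set_index("donor_id")
    out = []
    for donor_id, grp in df.groupby("donor_id", sort=False):
        periods = []
        for _, per in grp.groupby("period", sort=True):
            by_tracer = {}
            for row in per.itertuples(index=False):
                by_tracer[row.tracer] = TracerMeasurement(
                    tracer=row.tracer,
                    urinary_excretion_rate=row.urinary_excretion_rate,
                    plasma_concentration=row.plasma_concentration,
                    infusion_rate=row.infusion_rate)
            if set(by_tracer) != {"iothalamate", "hippurate"}:
                raise ClearanceError(f"donor {donor_id}: period needs both tracers")
            periods.append((by_tracer["iothalamate"], by_tracer["hippurate"]))
        res = mgfr_from_periods(periods, anth.loc[donor_id, "height"],
                                anth.loc[donor_id, "weight"])
        out.append((donor_id, res.mgfr_indexed))
    return pd.DataFrame(out, columns=["donor_id", "mgfr_pre"])
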