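"""Donor cohort data model and CSV I/O.

A cohort is a table of living kidney donors with demographics, the two
filtration biomarkers (plasma creatinine and cystatin C), optional 24-h
urinary creatinine excretion (the muscle-mass surrogate), and the measured
GFR before donation and — where available — three months after donor
nephrectomy.  All downstream stages (equation evaluation, agreement
statistics, subgroup construction) consume this one canonical table.

Units are fixed after load: creatinine µmol/l, cystatin C mg/l, excretion
mmol/24 h, GFR ml/min/1.73 m².  Missing optional values are held as NaN /
None, never as sentinel numbers; each analysis stage works on pairwise-
complete rows and reports its effective n.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .units import convert_units

FEMALE = "female"
MALE = "male"

_SEX_ALIASES = {
    "f": FEMALE, "female": FEMALE, "w": FEMALE, "v": FEMALE,
    "m": MALE, "male": MALE,
}

REQUIRED_COLUMNS = ("donor_id", "sex", "age", "plasma_creatinine", "plasma_cystatin_c")
OPTIONAL_COLUMNS = (
    "height", "weight", "urinary_creatinine_excretion",
    "cystatin_assay", "mgfr_pre", "mgfr_post",
)
ALL_COLUMNS = REQUIRED_COLUMNS + OPTIONAL_COLUMNS

#: canonical unit per convertible column
CANONICAL_UNITS = {
    "plasma_creatinine": "umol/l",
    "plasma_cystatin_c": "mg/l",
    "urinary_creatinine_excretion": "mmol",
}

_NUMERIC = (
    "age", "height", "weight", "plasma_creatinine", "plasma_cystatin_c",
    "urinary_creatinine_excretion", "mgfr_pre", "mgfr_post",
)


class CohortError(ValueError):
    """Fatal cohort-level problem (missing column, empty table, bad unit)."""


@dataclasses.dataclass
class DonorRecord:
    """One donor's demographics, biomarkers, excretion and measured GFR.

    Optional fields are ``None`` when not recorded.  Units are the canonical
    ones; invariants are enforced at construction.
    """

    donor_id: str
    sex: str
    age: float
    plasma_creatinine: float
    plasma_cystatin_c: float
    height: float | None = None          # cm
    weight: float | None = None          # kg
    urinary_creatinine_excretion: float | None = None  # mmol/24 h
    cystatin_assay: str | None = None
    mgfr_pre: float | None = None        # ml/min/1.73 m²
    mgfr_post: float | None = None       # ml/min/1.73 m²

    def __post_init__(self) -> None:
        if self.sex not in (FEMALE, MALE):
            raise ValueError(f"donor {self.donor_id}: sex must be female/male, got {self.sex!r}")
        if not self.age > 0:
            raise ValueError(f"donor {self.donor_id}: age must be positive")
        if self.height is not None and not (100 < self.height < 230):
            raise ValueError(f"donor {self.donor_id}: height {self.height} cm out of range")
        if self.weight is not None and not self.weight > 0:
            raise ValueError(f"donor {self.donor_id}: weight must be positive")
        for field in ("plasma_creatinine", "plasma_cystatin_c",
                      "urinary_creatinine_excretion", "mgfr_pre", "mgfr_post"):
            v = getattr(self, field)
            if v is not None and not v > 0:
                raise ValueError(f"donor {self.donor_id}: {field} must be positive, got {v}")


class CohortTable:
    """Ordered collection of :class:`DonorRecord` with a provenance note."""

    def __init__(self, df: pd.DataFrame, provenance: str = "unspecified"):
        df = df.copy().reset_index(drop=True)
        for col in ALL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df["donor_id"] = df["donor_id"].astype(str)
        if df["donor_id"].duplicated().any():
            dupes = df.loc[df["donor_id"].duplicated(), "donor_id"].tolist()
            raise CohortError(f"duplicate donor_id values: {dupes[:5]}")
        extras = [c for c in df.columns if c not in ALL_COLUMNS]
        self.df = df[list(ALL_COLUMNS) + extras]
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.df, other.df, check_dtype=False)
        except AssertionError:
            return False
        return True

    @classmethod
    def from_records(cls, records: Iterable[DonorRecord], provenance: str = "records") -> "CohortTable":
        rows = [dataclasses.asdict(r) for r in records]
        df = pd.DataFrame(rows, columns=list(ALL_COLUMNS))
        return cls(df, provenance)

    def records(self) -> list[DonorRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            kwargs = row._asdict()
            for k, v in kwargs.items():
                if isinstance(v, float) and math.isnan(v):
                    kwargs[k] = None
            if kwargs.get("cystatin_assay") is None or (
                isinstance(kwargs["cystatin_assay"], float) and math.isnan(kwargs["cystatin_assay"])
            ):
                kwargs["cystatin_assay"] = None
            out.append(DonorRecord(**kwargs))
        return out

    def write(self, path: str | Path) -> None:
        """Write the cohort as a canonical-unit CSV (UTF-8, header row)."""
        self.df.to_csv(path, index=False)


def _parse_sex(value: object) -> str:
    s = str(value).strip().lower()
    try:
        return _SEX_ALIASES[s]
    except KeyError:
        raise ValueError(f"unrecognized sex value {value!r}") from None


def read_cohort(path: str | Path, unit_overrides: Mapping[str, str] | None = None) -> CohortTable:
    """Read a donor cohort CSV, validate it and normalize units.

    Parameters
    ----------
    path
        Comma-separated UTF-8 file with a header row.  Required columns:
        ``donor_id, sex, age, plasma_creatinine, plasma_cystatin_c``.
    unit_overrides
        Mapping column name → unit the file is in (e.g.
        ``{"plasma_creatinine": "mg/dl"}``); values are converted to the
        canonical unit on load.  Unknown units are fatal.

    Rows whose required fields do not parse or violate the record
    invariants are dropped; per-row diagnostics are collected on the
    returned table's ``diagnostics`` attribute.
    """
    path = Path(path)
    if not path.exists():
        raise CohortError(f"cohort file not found: {path}")
    raw = pd.read_csv(path, dtype={"donor_id": str, "cystatin_assay": str})
    for col in REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise CohortError(f"missing required column: {col!r}")

    overrides = dict(unit_overrides or {})
    for col, unit in overrides.items():
        if col not in CANONICAL_UNITS:
            raise CohortError(f"unit override for non-convertible column {col!r}")
        raw[col] = [convert_units(v, unit, CANONICAL_UNITS[col]) for v in
                    pd.to_numeric(raw[col], errors="coerce")]

    rows, kept, diagnostics = [], [], []
    for i, row in raw.iterrows():
        kwargs: dict = {"donor_id": str(row["donor_id"])}
        try:
            kwargs["sex"] = _parse_sex(row["sex"])
            for col in _NUMERIC:
                if col in raw.columns:
                    v = pd.to_numeric(row[col], errors="coerce")
                    if pd.isna(v):
                        if col in REQUIRED_COLUMNS:
                            raise ValueError(f"unparseable required field {col!r}: {row[col]!r}")
                        kwargs[col] = None
                    else:
                        kwargs[col] = float(v)
            assay = row.get("cystatin_assay")
            kwargs["cystatin_assay"] = None if pd.isna(assay) else str(assay)
            rows.append(DonorRecord(**kwargs))
            kept.append(i)
        except ValueError as exc:
            diagnostics.append(f"row {i} (donor_id={row['donor_id']!r}): {exc}")
    table = CohortTable.from_records(rows, provenance=str(path))
    # extra columns (e.g. site labels for stratified reruns) ride along
    for col in raw.columns:
        if col not in ALL_COLUMNS:
            table.df[col] = raw.loc[kept, col].to_numpy()
    table.diagnostics = diagnostics
    return table
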