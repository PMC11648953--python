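"""High/low muscle-mass subgroup from 24-h urinary creatinine excretion.

Creatinine excretion over 24 h is a surrogate for total-body muscle mass.
To remove stature effects it is indexed to height, and quartile cut-points
are computed *within sex* (men excrete systematically more).  Donors in
the lowest or highest sex-specific quartile of the index form the
"extreme muscle mass" subgroup in which creatinine-based GFR estimates
are expected to perform worst.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cohort import CohortTable

LOWEST = "lowest_quartile"
HIGHEST = "highest_quartile"
MIDDLE = "middle"
MISSING = "missing_excretion"


class SubgroupError(ValueError):
    pass


@dataclasses.dataclass
class SubgroupAssignment:
    donor_id: str
    stratum: str
    indexed_excretion: float | None


def height_index_excretion(excretion: float, height: float, exponent: float = 1.0) -> float:
    """Excretion (mmol/24 h) divided by height in meters (raised to ``exponent``).

    Default exponent 1 gives mmol/24 h per m; exponent 2 allows
    height²-indexing to be explored.
    """
    if not (excretion > 0 and height > 0):
        raise SubgroupError("excretion and height must be positive")
    return excretion / (height / 100.0) ** exponent


def select_extreme_quartiles(cohort: CohortTable, exponent: float = 1.0) -> pd.DataFrame:
    """Assign every donor to a muscle-mass stratum.

    Within each sex, donors at or below the 25th percentile of
    height-indexed excretion go to ``lowest_quartile``, at or above the
    75th to ``highest_quartile`` (boundary ties included in the extreme
    stratum); the rest are ``middle``.  Donors without excretion or height
    are ``missing_excretion`` and take no part in the cut-points.

    Returns a frame (donor_id, sex, stratum, indexed_excretion).  A sex
    stratum with fewer than 4 evaluable donors is fatal — quartiles would
    be meaningless.
    """
    df = cohort.df.copy()
    if len(df) == 0:
        raise SubgroupError("empty cohort")
    evaluable = df["urinary_creatinine_excretion"].notna() & df["height"].notna()
    df["indexed_excretion"] = np.nan
    df.loc[evaluable, "indexed_excretion"] = [
        height_index_excretion(e, h, exponent)
        for e, h in zip(df.loc[evaluable, "urinary_creatinine_excretion"],
                        df.loc[evaluable, "height"])
    ]
    df["stratum"] = MISSING
    for sex in sorted(df["sex"].dropna().unique()):
        grp = df[evaluable & (df["sex"] == sex)]
        if len(grp) < 4:
            raise SubgroupError(f"sex stratum {sex!r} has only {len(grp)} evaluable donors (< 4)")
        q25, q75 = np.percentile(grp["indexed_excretion"], [25, 75])
        low = grp.index[grp["indexed_excretion"] <= q25]
        high = grp.index[grp["indexed_excretion"] >= q75]
        mid = grp.index.difference(low.union(high))
        df.loc[low, "stratum"] = LOWEST
        df.loc[high, "stratum"] = HIGHEST
        df.loc[mid, "stratum"] = MIDDLE
    return df[["donor_id", "sex", "stratum", "indexed_excretion"]]


def extreme_subgroup(cohort: CohortTable, exponent: float = 1.0) -> CohortTable:
    """The sub-cohort of donors in either extreme muscle-mass quartile."""
    assign = select_extreme_quartiles(cohort, exponent)
    keep = assign["stratum"].isin([LOWEST, HIGHEST])
    sub = cohort.df[keep.values]
    return CohortTable(sub, provenance=f"{cohort.provenance} | extreme muscle-mass quartiles")
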