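import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from donorgfr import CohortTable, SyntheticParams, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

# Hand-evaluated oracle panel: published piecewise formulas worked through
# by direct transcription, independent of the package implementation.
# Columns: equation, sex, age, creatinine (umol/l), cystatin C (mg/l), eGFR.
ORACLE_PANEL = [
    ("ckdepi_2009_creat", "female", 56, 80.0, None, 71.002449),
    ("ckdepi_2009_creat", "male",   56, 77.0, None, 96.430605),
    ("ckdepi_2009_creat", "female", 40, 50.0, None, 116.250746),
    ("ckdepi_2012_cys",   "female", 56, None, 0.89, 85.961519),
    ("ckdepi_2012_cys",   "male",   60, None, 1.20, 61.032724),
    ("ckdepi_2012_comb",  "female", 56, 80.0, 0.89, 78.486580),
    ("ckdepi_2012_comb",  "male",   56, 77.0, 0.89, 95.158418),
    ("ckdepi_2021_creat", "female", 56, 80.0, None, 74.535782),
    ("ckdepi_2021_creat", "male",   56, 77.0, None, 101.232868),
    ("ckdepi_2021_comb",  "male",   56, 77.0, 0.89, 100.304954),
    ("ckdepi_2021_comb",  "female", 45, 55.0, 0.70, 116.824477),
    ("ekfc_creat",        "male",   56, 77.0, None, 92.492773),
    ("ekfc_creat",        "female", 35, 50.0, None, 114.995674),
    ("ekfc_cys",          "male",   56, None, 0.89, 87.883146),
    ("ekfc_cys",          "female", 45, None, 0.70, 107.794666),
    ("ekfc_comb",         "male",   56, 77.0, 0.89, 90.187959),
]


@pytest.fixture(scope="session")
def default_cohort_10k() -> CohortTable:
    """The calibration-check cohort: default parameters, n=10,000, seed 1."""
    return generate_cohort(SyntheticParams(n=10_000, seed=1))


@pytest.fixture
def small_cohort() -> CohortTable:
    """Hand-written 3-donor cohort with complete fields."""
    df = pd.DataFrame({
        "donor_id": ["a", "b", "c"],
        "sex": ["female", "male", "female"],
        "age": [56.0, 48.0, 63.0],
        "height": [168.0, 182.0, 160.0],
        "weight": [70.0, 90.0, 62.0],
        "plasma_creatinine": [70.0, 85.0, 66.0],
        "plasma_cystatin_c": [0.85, 0.95, 1.02],
        "urinary_creatinine_excretion": [10.0, 16.0, 8.5],
        "cystatin_assay": ["gentian", "roche", "gentian"],
        "mgfr_pre": [95.0, 104.0, 78.0],
        "mgfr_post": [64.0, 70.0, 51.0],
    })
    return CohortTable(df, provenance="fixture")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240313)
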