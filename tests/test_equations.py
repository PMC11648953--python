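import numpy as np
import pytest
from hypothesis import given, strategies as st

from donorgfr import (CohortTable, apply_all_equations, evaluate_ckdepi,
                      evaluate_ekfc, evaluate_ekfc_combined, evaluate_equation)
from donorgfr.equations import (ALL_EQUATIONS, CKDEPI_EQUATIONS, EquationError,
                                ekfc_q, equation_markers, equation_specs)
from conftest import ORACLE_PANEL

SEXES = ("female", "male")


class TestOraclePanel:
    @pytest.mark.parametrize("name,sex,age,creat,cys,expected", ORACLE_PANEL)
    def test_matches_hand_evaluation(self, name, sex, age, creat, cys, expected):
        """Implementation agrees with independently worked published formulas."""
        got = evaluate_equation(name, sex, age, creatinine=creat, cystatin_c=cys)
        assert got == pytest.approx(expected, abs=0.1)

    def test_ekfc_combined_is_mean_of_components(self):
        a = evaluate_ekfc("ekfc_creat", "male", 56, 77.0)
        b = evaluate_ekfc("ekfc_cys", "male", 56, 0.89)
        assert evaluate_ekfc_combined("male", 56, 77.0, 0.89) == pytest.approx((a + b) / 2)
        assert evaluate_ekfc_combined("male", 56, 77.0, 0.89) == pytest.approx(
            (92.492773 + 87.883146) / 2, abs=0.1)


class TestContinuity:
    @pytest.mark.parametrize("name", CKDEPI_EQUATIONS)
    @pytest.mark.parametrize("sex", SEXES)
    @pytest.mark.parametrize("age", [25, 40, 56, 70])
    def test_ckdepi_continuous_at_kappa(self, name, sex, age):
        spec = equation_specs()[name]
        eps = 1e-9
        for marker in spec["markers"]:
            kappa = spec[marker]["kappa"][sex]
            if marker == "creatinine":
                kappa *= 88.4  # kappa is in mg/dl; inputs are umol/l
            kwargs = {m: (spec[m]["kappa"][sex] * (88.4 if m == "creatinine" else 1.0))
                      for m in spec["markers"]}
            lo = dict(kwargs, **{marker: kappa * (1 - eps)})
            hi = dict(kwargs, **{marker: kappa * (1 + eps)})
            v_lo = evaluate_ckdepi(name, sex, age, creatinine=lo.get("creatinine"),
                                   cystatin_c=lo.get("cystatin_c"))
            v_hi = evaluate_ckdepi(name, sex, age, creatinine=hi.get("creatinine"),
                                   cystatin_c=hi.get("cystatin_c"))
            assert v_lo == pytest.approx(v_hi, rel=1e-8)

    @pytest.mark.parametrize("name,marker_kw", [("ekfc_creat", "creatinine"),
                                                ("ekfc_cys", "cystatin_c")])
    @pytest.mark.parametrize("sex", SEXES)
    @pytest.mark.parametrize("age", [25, 40, 56, 70])
    def test_ekfc_continuous_at_q(self, name, marker_kw, sex, age):
        q = ekfc_q(name, sex, age)
        eps = 1e-9
        v_lo = evaluate_ekfc(name, sex, age, q * (1 - eps))
        v_hi = evaluate_ekfc(name, sex, age, q * (1 + eps))
        assert v_lo == pytest.approx(v_hi, rel=1e-8)

    @pytest.mark.parametrize("sex", SEXES)
    def test_ekfc_at_q_and_onset_age_equals_intercept(self, sex):
        """At marker = Q and age = 40 both the power and age terms vanish."""
        assert evaluate_ekfc("ekfc_creat", sex, 40.0, ekfc_q("ekfc_creat", sex, 40.0)) \
            == pytest.approx(107.3)


class TestMonotonicity:
    @given(st.sampled_from(ALL_EQUATIONS), st.sampled_from(SEXES),
           st.floats(min_value=25, max_value=85),
           st.floats(min_value=40, max_value=200),
           st.floats(min_value=0.5, max_value=2.5))
    def test_strictly_decreasing_in_each_marker(self, name, sex, age, creat, cys):
        def ev(c, y):
            return evaluate_equation(name, sex, age, creatinine=c, cystatin_c=y)
        markers = equation_markers(name)
        if "creatinine" in markers:
            assert ev(creat * 1.1, cys) < ev(creat, cys)
        if "cystatin_c" in markers:
            assert ev(creat, cys * 1.1) < ev(creat, cys)

    @given(st.sampled_from(ALL_EQUATIONS), st.sampled_from(SEXES),
           st.floats(min_value=25, max_value=80),
           st.floats(min_value=40, max_value=200),
           st.floats(min_value=0.5, max_value=2.5))
    def test_non_increasing_in_age(self, name, sex, age, creat, cys):
        v1 = evaluate_equation(name, sex, age, creatinine=creat, cystatin_c=cys)
        v2 = evaluate_equation(name, sex, age + 5, creatinine=creat, cystatin_c=cys)
        assert v2 <= v1 + 1e-12


class TestErrors:
    def test_missing_marker_named(self):
        with pytest.raises(EquationError, match="cystatin_c"):
            evaluate_equation("ckdepi_2012_cys", "female", 56, creatinine=80.0)

    def test_non_positive_marker_fatal(self):
        with pytest.raises(EquationError):
            evaluate_equation("ckdepi_2009_creat", "male", 56, creatinine=0.0)

    def test_unknown_equation(self):
        with pytest.raises(EquationError, match="unknown"):
            evaluate_equation("mdrd", "male", 56, creatinine=80.0)


class TestApplyAllEquations:
    def test_full_cohort_gives_eight_rows_per_donor(self, small_cohort):
        out = apply_all_equations(small_cohort)
        assert len(out) == 3 * 8
        assert set(out["equation"]) == set(ALL_EQUATIONS)

    def test_missing_cystatin_skips_cystatin_equations(self, small_cohort):
        df = small_cohort.df.copy()
        df.loc[0, "plasma_cystatin_c"] = np.nan
        out = apply_all_equations(CohortTable(df))
        per_donor = out.groupby("donor_id").size()
        assert per_donor["a"] == 3  # the creatinine-only equations
        assert per_donor["b"] == 8

    def test_empty_cohort_empty_result(self):
        import pandas as pd
        out = apply_all_equations(CohortTable(pd.DataFrame(columns=["donor_id"])))
        assert len(out) == 0
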