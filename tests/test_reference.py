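"""LMS z-scoring: transform identities, interpolation, inversion, table I/O."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

import growthrisk as gr
from growthrisk.errors import (
    AgeRangeError,
    DomainError,
    ReferenceTableError,
)
from growthrisk.reference import (
    Measurement,
    lms_inverse,
    lms_transform,
    load_reference,
    parse_length,
    parse_weight,
)


class TestLMSTransform:
    def test_value_at_median_is_zero(self):
        assert lms_transform(16.0, -0.5, 16.0, 0.08) == 0.0

    def test_l_equal_one_reduces_to_relative_deviation(self):
        # L=1: z = (x/M - 1)/S
        assert lms_transform(11.0, 1.0, 10.0, 0.1) == pytest.approx(1.0)

    def test_box_cox_value(self):
        # ((18/16)^-0.5 - 1) / (-0.5 * 0.08), checked against numeric
        # inversion of the transform
        assert lms_transform(18.0, -0.5, 16.0, 0.08) == pytest.approx(1.4298, abs=1e-4)

    def test_log_limit_continuity(self):
        near = lms_transform(18.0, 1e-9, 16.0, 0.08)
        exact = math.log(18.0 / 16.0) / 0.08
        assert near == pytest.approx(exact, rel=1e-6)

    def test_nonpositive_value_rejected(self):
        with pytest.raises(DomainError):
            lms_transform(0.0, -0.5, 16.0, 0.08)

    @given(z=st.floats(-4, 4), L=st.floats(-2, 2), M=st.floats(1, 30),
           S=st.floats(0.01, 0.2))
    @settings(max_examples=200, deadline=None)
    def test_inverse_round_trip(self, z, L, M, S):
        # the Box-Cox family only attains z with 1 + L*S*z > 0
        assume(1.0 + L * S * z > 1e-3)
        x = lms_inverse(z, L, M, S)
        assert lms_transform(x, L, M, S) == pytest.approx(z, abs=1e-9)

    @given(L=st.floats(-2, 2), M=st.floats(1, 30), S=st.floats(0.01, 0.2),
           x1=st.floats(1, 40), x2=st.floats(1, 40))
    @settings(max_examples=200, deadline=None)
    def test_strictly_increasing_in_value(self, L, M, S, x1, x2):
        if x1 == x2:
            return
        lo, hi = sorted([x1, x2])
        assert lms_transform(lo, L, M, S) < lms_transform(hi, L, M, S)


class TestCentileBridge:
    def test_median(self):
        assert gr.z_to_centile(0.0) == pytest.approx(50.0)

    def test_91st_centile(self):
        # inverse normal CDF at 0.91, cross-checked by bisection on the CDF
        assert gr.centile_to_z(91.0) == pytest.approx(1.3408, abs=1e-4)

    def test_round_trip(self):
        assert gr.centile_to_z(gr.z_to_centile(1.7)) == pytest.approx(1.7, abs=1e-9)

    @pytest.mark.parametrize("bad", [0.0, 100.0, -3.0, 104.0])
    def test_centile_domain(self, bad):
        with pytest.raises(DomainError):
            gr.centile_to_z(bad)


class TestReferenceSet:
    def test_load_reads_back_knots(self, tmp_path):
        df = pd.DataFrame({
            "measurement": ["weight"] * 6,
            "sex": ["male"] * 3 + ["female"] * 3,
            "age_days": [0, 100, 200] * 2,
            "L": [1.0] * 6,
            "M": [3.5, 5.5, 7.0, 3.3, 5.2, 6.7],
            "S": [0.12] * 6,
        })
        path = tmp_path / "lms.csv"
        df.to_csv(path, index=False)
        refs = load_reference(path)
        curve = refs.get_curve("weight", "male")
        assert len(curve.age_days) == 3
        assert curve.zscore(5.5, 100) == 0.0

    def test_duplicated_age_rejected(self, tmp_path):
        df = pd.DataFrame({
            "measurement": ["weight"] * 3, "sex": ["male"] * 3,
            "age_days": [0, 100, 100], "L": [1.0] * 3,
            "M": [3.5, 5.5, 5.6], "S": [0.12] * 3,
        })
        path = tmp_path / "lms.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ReferenceTableError, match="100"):
            load_reference(path)

    def test_missing_sex_rejected(self, tmp_path):
        df = pd.DataFrame({
            "measurement": ["weight"] * 2, "sex": ["male"] * 2,
            "age_days": [0, 100], "L": [1.0] * 2, "M": [3.5, 5.5], "S": [0.12] * 2,
        })
        path = tmp_path / "lms.csv"
        df.to_csv(path, index=False)
        refs = load_reference(path)
        with pytest.raises(ReferenceTableError, match="female"):
            refs.get_curve("weight", "female")

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "lms.csv"
        pd.DataFrame({"measurement": [], "sex": [], "age_days": []}).to_csv(
            path, index=False)
        with pytest.raises(ReferenceTableError, match="missing columns"):
            load_reference(path)

    def test_nonpositive_m_names_row(self):
        with pytest.raises(ReferenceTableError, match="row 1"):
            gr.LMSReference("weight", "male", [0, 30], [1, 1], [3.5, -1.0], [0.1, 0.1])

    def test_age_outside_span(self, refs):
        with pytest.raises(AgeRangeError):
            refs.get_curve("weight", "male").zscore(10.0, 10_000)

    def test_interpolation_consistent_at_knots(self, refs):
        curve = refs.get_curve("weight", "female")
        i = 5
        knot_z = gr.reference.lms_transform(
            7.0, curve.L[i], curve.M[i], curve.S[i])
        assert curve.zscore(7.0, curve.age_days[i]) == pytest.approx(knot_z)

    def test_value_for_z_inverts(self, refs):
        curve = refs.get_curve("bmi", "male")
        x = curve.value_for_z(1.25, 400.5)
        assert curve.zscore(x, 400.5) == pytest.approx(1.25, rel=1e-6)

    def test_save_load_round_trip(self, refs, tmp_path):
        path = tmp_path / "out.csv"
        refs.save(path)
        again = load_reference(path)
        c1 = refs.get_curve("length", "female")
        c2 = again.get_curve("length", "female")
        assert c2.zscore(70.0, 300) == pytest.approx(c1.zscore(70.0, 300), rel=1e-9)


class TestMeasurementToZ:
    def test_weight_only(self, refs):
        m = Measurement("a", "f", 200, weight_kg=6.5)
        z = gr.measurement_to_z(m, refs)
        assert z.weight_z is not None
        assert z.length_z is None and z.bmi_z is None

    def test_bmi_arithmetic(self):
        m = Measurement("a", "m", 200, weight_kg=8.0, length_cm=70.0)
        assert m.bmi == pytest.approx(8.0 / 0.70**2)

    def test_median_infant_all_zero(self, refs):
        age = 274
        w = refs.get_curve("weight", "female").value_for_z(0.0, age)
        l = refs.get_curve("length", "female").value_for_z(0.0, age)
        z = gr.measurement_to_z(
            Measurement("a", "f", age, weight_kg=w, length_cm=l), refs)
        assert z.weight_z == pytest.approx(0.0, abs=1e-9)
        assert z.length_z == pytest.approx(0.0, abs=1e-9)
        # BMI median is derived from the weight/length medians, so the
        # median infant sits on the BMI median too
        assert z.bmi_z == pytest.approx(0.0, abs=1e-6)

    def test_requires_some_measurement(self):
        with pytest.raises(DomainError):
            Measurement("a", "f", 200)


class TestUnitParsing:
    @pytest.mark.parametrize("raw,kg", [
        ("3.2kg", 3.2), ("7lb", 7 * 0.45359237), (4.1, 4.1), ("8", 8.0),
    ])
    def test_weight(self, raw, kg):
        assert parse_weight(raw) == pytest.approx(kg)

    @pytest.mark.parametrize("raw,cm", [
        ("165cm", 165.0), ("65in", 165.1), ("5ft6in", 167.64), ("5ft", 152.4),
        (70, 70.0),
    ])
    def test_length(self, raw, cm):
        assert parse_length(raw) == pytest.approx(cm)

    def test_unknown_unit(self):
        from growthrisk.errors import UnitError
        with pytest.raises(UnitError):
            parse_weight("3.2 stone")
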