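"""Vector analysis, Redfield classification and distance matrices."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from enzlim.stoichiometry import (
    AcquisitionSums,
    DegenerateProfileError,
    EnzymeProfile,
    LimitationClass,
    ValidationError,
    acquisition_sums,
    element_cycle_distance,
    scalar_difference_matrix,
    vector_limitation,
    water_limitation,
)

positive = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)


def make_profiles(values, prefix="S"):
    return [
        EnzymeProfile(f"{prefix}{i}", *row) for i, row in enumerate(values)
    ]


class TestAcquisitionSums:
    @pytest.mark.parametrize(
        "activities, expected",
        [
            ((458.12, 159.11, 114.38, 24.9, 200.0), (617.23, 139.28, 200.0)),
            ((0, 0, 0, 0, 0), (0, 0, 0)),
            ((1, 1, 1, 1, 1), (2, 2, 1)),
        ],
    )
    def test_sums_components(self, activities, expected):
        s = acquisition_sums(EnzymeProfile("s", *activities))
        assert (s.c_acq, s.n_acq, s.p_acq) == pytest.approx(expected)

    def test_negative_activity_names_enzyme(self):
        with pytest.raises(ValidationError, match="nag"):
            EnzymeProfile("s", 1, 1, -2, 1, 1)


class TestVectorLimitation:
    def test_balanced_point(self):
        v = vector_limitation(AcquisitionSums(100, 100, 100))
        assert v.x == v.y == 0.5
        assert v.vector_length == pytest.approx(math.sqrt(0.5), abs=1e-12)
        assert v.vector_angle_deg == pytest.approx(45.0, abs=1e-12)
        assert v.n_limitation == pytest.approx(45.0, abs=1e-12)
        assert v.limitation_class is LimitationClass.BALANCED

    def test_p_limited_example(self):
        # frozen from an independent hand-trig computation
        v = vector_limitation(AcquisitionSums(600, 150, 300))
        assert v.x == pytest.approx(0.6666666667)
        assert v.y == pytest.approx(0.8)
        assert v.vector_length == pytest.approx(1.0413666235, abs=1e-9)
        assert v.vector_angle_deg == pytest.approx(50.1944289077, abs=1e-9)
        assert v.n_limitation == pytest.approx(39.8055710923, abs=1e-9)
        assert v.limitation_class is LimitationClass.P_LIMITED

    def test_survey_mean_profile(self):
        # more P- than N-acquisition effort puts the angle just above 45°
        v = vector_limitation(AcquisitionSums(617.23, 139.28, 200))
        assert v.vector_angle_deg == pytest.approx(47.2095612458, abs=1e-9)
        assert v.limitation_class is LimitationClass.P_LIMITED
        # ... and shrinking P acquisition below N acquisition flips the call
        v2 = vector_limitation(AcquisitionSums(617.23, 139.28, 100))
        assert v2.vector_angle_deg < 45
        assert v2.limitation_class is LimitationClass.N_LIMITED

    @pytest.mark.parametrize("bad", [(0, 1, 1), (1, 0, 1), (1, 1, 0), (-1, 1, 1)])
    def test_degenerate_sums_rejected(self, bad):
        with pytest.raises(DegenerateProfileError):
            vector_limitation(AcquisitionSums(*bad))

    @given(c=positive, n=positive, p=positive)
    def test_complement_and_bounds(self, c, n, p):
        v = vector_limitation(AcquisitionSums(c, n, p))
        assert v.n_limitation + v.vector_angle_deg == pytest.approx(90.0, abs=1e-12)
        assert 0 < v.vector_length <= math.sqrt(2) + 1e-12
        assert 0 < v.vector_angle_deg < 90

    @given(c=positive, n=positive, p=positive,
           k=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, c, n, p, k):
        v1 = vector_limitation(AcquisitionSums(c, n, p))
        v2 = vector_limitation(AcquisitionSums(k * c, k * n, k * p))
        assert v2.x == pytest.approx(v1.x, rel=1e-9)
        assert v2.vector_length == pytest.approx(v1.vector_length, rel=1e-9)
        assert v2.vector_angle_deg == pytest.approx(v1.vector_angle_deg, abs=1e-9)
        assert v2.limitation_class == v1.limitation_class

    @given(c=positive, n=positive, p=positive)
    def test_axis_swap_identity(self, c, n, p):
        """Swapping N and P acquisition mirrors the angle about 45°."""
        v = vector_limitation(AcquisitionSums(c, n, p))
        w = vector_limitation(AcquisitionSums(c, p, n))
        assert v.vector_angle_deg + w.vector_angle_deg == pytest.approx(
            90.0, abs=1e-9
        )

    def test_monotonicity(self):
        base = AcquisitionSums(100.0, 80.0, 60.0)
        v0 = vector_limitation(base)
        more_p = vector_limitation(AcquisitionSums(100.0, 80.0, 90.0))
        assert more_p.vector_angle_deg > v0.vector_angle_deg
        more_n = vector_limitation(AcquisitionSums(100.0, 120.0, 60.0))
        assert more_n.vector_angle_deg < v0.vector_angle_deg
        more_c = vector_limitation(AcquisitionSums(150.0, 80.0, 60.0))
        assert more_c.vector_length > v0.vector_length

    def test_balanced_tolerance_band(self):
        v = vector_limitation(AcquisitionSums(100, 100.0001, 100), tolerance=1.0)
        assert v.limitation_class is LimitationClass.BALANCED
        v = vector_limitation(AcquisitionSums(100, 100.0001, 100), tolerance=0.0)
        assert v.limitation_class is not LimitationClass.BALANCED


class TestWaterLimitation:
    def test_boundary_goes_to_n_side(self):
        tp = 0.04
        tn = 16 * 14.007 * tp / 30.974  # molar ratio exactly 16
        w = water_limitation(tn, tp)
        assert w.np_molar_ratio == pytest.approx(16.0, abs=1e-12)
        assert w.water_limitation is LimitationClass.N_LIMITED

    def test_p_limited_lake_water(self):
        w = water_limitation(1.0, 0.04)
        assert w.np_molar_ratio == pytest.approx(55.283, abs=0.01)
        assert w.water_limitation is LimitationClass.P_LIMITED

    def test_n_limited_water(self):
        w = water_limitation(0.1, 1.0)
        assert w.np_molar_ratio == pytest.approx(0.2211, abs=0.001)
        assert w.water_limitation is LimitationClass.N_LIMITED

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            water_limitation(0.0, 0.04)


class TestElementCycleDistance:
    def test_identical_profiles_zero(self):
        profs = make_profiles([(1, 2, 3, 4, 5), (1, 2, 3, 4, 5), (9, 2, 3, 4, 5)])
        d = element_cycle_distance(profs, standardize=False)
        assert d["S0", "S1"] == 0.0

    def test_3_4_5_triangle_raw(self):
        profs = make_profiles([(1, 2, 3, 4, 5), (4, 2, 7, 4, 5)])
        d = element_cycle_distance(profs, standardize=False)
        assert d["S0", "S1"] == pytest.approx(5.0)

    def test_matches_naive_double_loop(self, rng):
        data = rng.uniform(1, 100, size=(6, 5))
        profs = make_profiles(data)
        for standardize in (True, False):
            mat = data.copy()
            if standardize:
                mat = (mat - mat.mean(0)) / mat.std(0, ddof=1)
            d = element_cycle_distance(profs, standardize=standardize)
            for i in range(6):
                for j in range(6):
                    brute = math.sqrt(sum((mat[i, k] - mat[j, k]) ** 2
                                          for k in range(5)))
                    assert d[f"S{i}", f"S{j}"] == pytest.approx(brute, abs=1e-10)

    def test_zero_variance_column_errors(self):
        profs = make_profiles([(1, 2, 3, 4, 5), (2, 2, 4, 5, 6)])
        with pytest.raises(ValidationError, match="cbh"):
            element_cycle_distance(profs, standardize=True)


class TestScalarDifferenceMatrix:
    def test_constant_values(self):
        d = scalar_difference_matrix([5, 5, 5])
        assert np.all(d.data == 0)

    def test_pairwise_abs_differences(self):
        d = scalar_difference_matrix([0, 1, 3])
        assert d["0", "1"] == 1
        assert d["0", "2"] == 3
        assert d["1", "2"] == 2

    def test_too_few_values(self):
        with pytest.raises(ValidationError):
            scalar_difference_matrix([1.0])
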