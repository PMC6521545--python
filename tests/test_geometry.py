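"""Geometric core: rotations, axial projection, functional anteversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cupfa import (
    ContractError,
    CupPlan,
    DegenerateOrientationError,
    PelvicTilt,
    SpinopelvicProfile,
    ValidationError,
    Vector3,
    apply_pelvic_tilt,
    axial_anteversion,
    cup_normal,
    delta_fa,
    functional_anteversion,
    profile_fa,
)
from cupfa.geometry import ValidationWindow, closed_form_fa


# --- independent oracle: explicit rotation-matrix composition ---------------

def _ry(deg):
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rz(deg):
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _rx(deg):
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def matrix_oracle_fa(inclination, anteversion, tilt):
    """FA by composing the three rotations as explicit 3x3 matrices."""
    v = _rx(tilt) @ _rz(anteversion) @ _ry(-inclination) @ np.array([0.0, 0.0, -1.0])
    return math.degrees(math.atan2(v[1], v[0]))


# --- cup_normal --------------------------------------------------------------

def test_cup_normal_components_match_spherical_form():
    wide = ValidationWindow(inclination_deg=(0.5, 89.5))
    for i, a in [(40, 20), (30, 15), (60, 25), (10, -10), (80, 50)]:
        v = cup_normal(CupPlan(i, a), wide)
        ir, ar = math.radians(i), math.radians(a)
        assert v.x == pytest.approx(math.sin(ir) * math.cos(ar), abs=1e-12)
        assert v.y == pytest.approx(math.sin(ir) * math.sin(ar), abs=1e-12)
        assert v.z == pytest.approx(-math.cos(ir), abs=1e-12)
        assert abs(v.norm - 1.0) < 1e-12


def test_cup_normal_limiting_orientations():
    # inclination alone swings the neutral (inferior) normal laterally
    near_zero = _ry(0) @ np.array([0, 0, -1.0])
    assert np.allclose(near_zero, [0, 0, -1])
    quarter = _ry(-90) @ np.array([0, 0, -1.0])
    assert np.allclose(quarter, [1, 0, 0], atol=1e-12)


def test_anteversion_rotation_preserves_axial_polar_angle():
    # rotating about the vertical axis by A sets the axial polar angle to A
    v = cup_normal(CupPlan(40, 20))
    assert math.degrees(math.atan2(v.y, v.x)) == pytest.approx(20.0, abs=1e-12)


def test_cup_normal_rejects_out_of_window_angles():
    with pytest.raises(ValidationError, match="inclination_deg"):
        cup_normal(CupPlan(5, 20))
    with pytest.raises(ValidationError, match="anteversion_deg"):
        cup_normal(CupPlan(40, 60))
    with pytest.raises(ValidationError):
        CupPlan(95, 20)  # hard bound regardless of window


# --- apply_pelvic_tilt -------------------------------------------------------

def test_pelvic_tilt_identity_quarter_turn_and_inverse():
    v = Vector3(0.0, 0.0, -1.0)
    assert apply_pelvic_tilt(v, PelvicTilt(0)) == pytest.approx(v)
    turned = apply_pelvic_tilt(v, PelvicTilt(90))
    assert turned == pytest.approx((0.0, 1.0, 0.0), abs=1e-12)
    w = Vector3(0.0, 1.0, 0.0)
    back = apply_pelvic_tilt(apply_pelvic_tilt(w, PelvicTilt(37.5)), PelvicTilt(-37.5))
    assert back == pytest.approx((0.0, 1.0, 0.0), abs=1e-12)


def test_positive_tilt_moves_inferior_normal_anteriorly():
    v = apply_pelvic_tilt(Vector3(0.0, 0.0, -1.0), PelvicTilt(10))
    assert v.y > 0


def test_apply_pelvic_tilt_rejects_non_unit_vector():
    with pytest.raises(ContractError):
        apply_pelvic_tilt(Vector3(0.0, 0.0, -2.0), PelvicTilt(10))


# --- axial_anteversion -------------------------------------------------------

@pytest.mark.parametrize(
    "v, expected",
    [
        (Vector3(1.0, 0.0, 0.0), 0.0),
        (Vector3(1.0, 0.0, -0.5), 0.0),
        (Vector3(0.5, 0.5, -0.707), 45.0),
    ],
)
def test_axial_anteversion_of_simple_projections(v, expected):
    assert axial_anteversion(v) == pytest.approx(expected, abs=1e-12)


def test_axial_anteversion_degenerate_when_normal_not_lateral():
    with pytest.raises(DegenerateOrientationError):
        axial_anteversion(Vector3(0.0, 0.0, -1.0))
    with pytest.raises(DegenerateOrientationError):
        axial_anteversion(Vector3(-0.5, 0.5, 0.707))


def test_planned_position_recovery():
    # without tilt, the axial angle of the cup normal is the planned anteversion
    for i in (15, 40, 75):
        for a in (-10, 0, 20, 50):
            v = cup_normal(CupPlan(i, a))
            assert axial_anteversion(v) == pytest.approx(a, abs=1e-9)


# --- functional_anteversion / delta_fa ---------------------------------------

def test_worked_fa_values():
    """The two standard worked examples of the model, to one decimal."""
    assert round(functional_anteversion(CupPlan(40, 20), PelvicTilt(15)), 1) == 34.2
    assert round(functional_anteversion(CupPlan(35, 20), PelvicTilt(6)), 1) == 27.5


def test_no_tilt_returns_planned_anteversion():
    for i, a in [(30, 15), (45, 0), (60, 25)]:
        assert functional_anteversion(CupPlan(i, a), PelvicTilt(0)) == pytest.approx(
            a, abs=1e-12
        )
        assert delta_fa(CupPlan(i, a), PelvicTilt(0)) == pytest.approx(0.0, abs=1e-12)


def test_delta_fa_worked_value_and_sign_asymmetry():
    assert round(delta_fa(CupPlan(40, 20), PelvicTilt(15)), 1) == 14.2
    up = delta_fa(CupPlan(40, 20), PelvicTilt(15))
    down = delta_fa(CupPlan(40, 20), PelvicTilt(-15))
    assert down < 0 < up
    # FA is nonlinear in PT: anterior and posterior tilt are not mirror images
    assert abs(up) != pytest.approx(abs(down), abs=1e-6)


def test_vector_pipeline_agrees_with_closed_form():
    rng = np.random.default_rng(20190502)
    for _ in range(200):
        i = rng.uniform(10, 80)
        a = rng.uniform(-10, 50)
        t = rng.uniform(-45, 60)
        via_vectors = functional_anteversion(CupPlan(i, a), PelvicTilt(t))
        assert via_vectors == pytest.approx(closed_form_fa(i, a, t), abs=1e-9)


def test_rotation_matrix_oracle_equivalence():
    """1,000 random points in the validation window vs the 3x3-matrix oracle."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        i = rng.uniform(10, 80)
        a = rng.uniform(-10, 50)
        t = rng.uniform(-45, 60)
        assert functional_anteversion(CupPlan(i, a), PelvicTilt(t)) == pytest.approx(
            matrix_oracle_fa(i, a, t), abs=1e-9
        )


@given(
    i=st.floats(10, 80),
    a=st.floats(-10, 50),
    t=st.floats(-45, 60),
)
@settings(max_examples=200, derandomize=True)
def test_norm_preserved_and_oracle_agreement_property(i, a, t):
    v = apply_pelvic_tilt(cup_normal(CupPlan(i, a)), PelvicTilt(t))
    assert abs(v.norm - 1.0) < 1e-12
    if v.x > 1e-9:
        assert axial_anteversion(v) == pytest.approx(matrix_oracle_fa(i, a, t), abs=1e-9)


def test_fa_monotone_in_tilt_on_grid_domain():
    for i in range(30, 61, 5):
        for a in range(15, 26, 5):
            fas = [
                functional_anteversion(CupPlan(i, a), PelvicTilt(t))
                for t in range(0, 31)
            ]
            assert all(b > x for x, b in zip(fas, fas[1:]))


# --- profile_fa --------------------------------------------------------------

def test_profile_fa_change_is_difference_and_positive_for_posterior_motion():
    plan = CupPlan(40, 20)
    fo = profile_fa(plan, SpinopelvicProfile.from_degrees(0.3, 25.8))
    assert fo.fa_change_deg == fo.fa_sitting_deg - fo.fa_standing_deg
    assert fo.fa_change_deg > 0

    same = profile_fa(plan, SpinopelvicProfile.from_degrees(12.0, 12.0))
    assert same.fa_change_deg == 0

    cohort = profile_fa(plan, SpinopelvicProfile.from_degrees(4.2, 23.4))
    assert math.isfinite(cohort.fa_standing_deg)
    assert cohort.fa_sitting_deg > cohort.fa_standing_deg
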