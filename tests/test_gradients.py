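import numpy as np
import pytest

from reachframes.gradients import (activity_matrix, axial_distance_deg,
                                   epoch_samples, eye_axis_deg,
                                   gradient_series, halved_angle_deg,
                                   hand_axis_deg, pair_conditions,
                                   population_resultant,
                                   unit_gradient_resultant)
from reachframes.units import UnitSpec


@pytest.fixture
def hand_units():
    return [UnitSpec(f"h{k}", "hand", u=u)
            for k, u in enumerate((-15.0, 0.0, 15.0))]


def test_constant_matrix_has_zero_resultant():
    assert np.allclose(unit_gradient_resultant(np.full((5, 5), 7.0)), 0.0)


def test_column_dependent_matrix_points_along_column_axis():
    x = np.arange(5.0) * 10.0
    M = np.tile(x, (5, 1))  # depends only on the column parameter
    vec = unit_gradient_resultant(M)
    # the 90-deg column axis doubles to 180 deg: a vector along -x
    assert vec[1] == pytest.approx(0.0, abs=1e-12)
    assert vec[0] < 0
    assert halved_angle_deg(vec) == pytest.approx(90.0)


def test_activity_matrix_layout(hand_unit):
    """Rows follow the first pair parameter: for a hand-centered unit the
    T x H matrix is constant along diagonals of constant T - H."""
    M = activity_matrix(hand_unit, ("T", "H"), t=-0.5)
    for off in range(-2, 3):
        diag = np.diagonal(M, offset=off)
        assert np.allclose(diag, diag[0])
    with pytest.raises(ValueError):
        activity_matrix(hand_unit, ("T", "X"), t=0.0)


def test_hand_unit_pretarget_matrix_is_flat(hand_unit):
    M = activity_matrix(hand_unit, ("T", "H"), t=-1.5)
    assert np.allclose(M, 30.0)


def test_hand_unit_delay_resultant_on_displacement_axis(hand_unit):
    vec = unit_gradient_resultant(activity_matrix(hand_unit, ("T", "H"),
                                                  t=-0.5))
    assert axial_distance_deg(halved_angle_deg(vec),
                              hand_axis_deg(("T", "H"))) < 5.0


def test_angle_doubling_prevents_antidiagonal_cancellation(hand_unit):
    """Raw gradients of a T - H dependent matrix point along both
    anti-diagonal directions and cancel; doubling makes them reinforce."""
    M = activity_matrix(hand_unit, ("T", "H"), t=-0.5)
    g_r = np.gradient(M, 10.0, axis=0)
    g_c = np.gradient(M, 10.0, axis=1)
    naive = np.array([g_r.sum(), g_c.sum()])
    doubled = unit_gradient_resultant(M)
    assert np.hypot(*naive) < np.hypot(*doubled)


def test_population_resultant_degenerates_at_offset(hand_units):
    delay = population_resultant(hand_units, ("T", "H"), -0.5)
    offset = population_resultant(hand_units, ("T", "H"), 1.0)
    assert np.hypot(*offset) < 0.01 * np.hypot(*delay)


def test_hybrid_weights_must_sum_to_one(hand_units):
    with pytest.raises(ValueError):
        population_resultant(hand_units, ("T", "H"), 0.0,
                             weights={"hand": 0.5})


def test_epoch_samples_are_unit_length(hand_units):
    series = gradient_series(hand_units, pairs=(("T", "H"),))
    samples = epoch_samples(series)["TxH"]
    go = samples["go"]
    assert np.hypot(go["x"], go["y"]) == pytest.approx(1.0, abs=1e-9)
    pre = samples["pre_target"]
    assert np.hypot(pre["x"], pre["y"]) == 0.0  # zero stays zero


def test_epoch_outside_series_errors(hand_units):
    series = gradient_series(hand_units, times=(0.0, 1.0),
                             pairs=(("T", "H"),))
    with pytest.raises(ValueError):
        epoch_samples(series)


def test_pair_conditions_fix_third_parameter():
    conds = pair_conditions(("H", "E"), fixed_value=0.0)
    assert np.all(conds.T == 0.0)
    assert len(conds) == 25


@pytest.mark.parametrize("pair", [("T", "H"), ("T", "E"), ("H", "E")])
def test_reference_axes_are_axially_distinct(pair):
    assert axial_distance_deg(eye_axis_deg(pair), hand_axis_deg(pair)) >= 45.0


def test_axial_distance_wraps():
    assert axial_distance_deg(-80.0, 90.0) == pytest.approx(10.0)
    assert axial_distance_deg(45.0, 45.0) == 0.0
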