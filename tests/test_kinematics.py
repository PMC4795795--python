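import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reachframes.kinematics import (TaskCondition, desired_trajectory,
                                    displacement_vector,
                                    phenomenological_hand_position, phi, psi)

positions = st.floats(-45, 45, allow_nan=False)
movement_times = st.floats(0, 1, allow_nan=False)
task_times = st.floats(-2, 1, allow_nan=False)


@pytest.mark.parametrize("t, expected", [
    (-2.0, 1.0),   # back-extrapolated pre-target value
    (-0.5, 1.0),   # delay period
    (0.0, 1.0),    # movement onset (delay branch closed at 0)
    (0.5, 0.5),    # midway through the intended movement
    (1.0, 0.0),    # movement offset
])
def test_psi_piecewise_values(t, expected):
    assert psi(t) == pytest.approx(expected)
    assert phi(t) == pytest.approx(1.0 - expected)


@pytest.mark.parametrize("t", [-2.5, 1.5, 10.0])
def test_psi_domain_error(t):
    with pytest.raises(ValueError):
        psi(t)


def test_psi_smooth_form_shares_endpoints_and_monotonicity():
    ts = np.linspace(-2, 1, 61)
    smooth = psi(ts, form="smooth")
    assert smooth[ts <= 0].max() == 1.0
    assert psi(1.0, form="smooth") == 0.0
    assert np.all(np.diff(smooth) <= 1e-12)
    with pytest.raises(ValueError):
        psi(0.5, form="nope")


@pytest.mark.parametrize("cond, expected", [
    (TaskCondition(E=0, H=-10, T=20), 30.0),
    (TaskCondition(E=5, H=12, T=12), 0.0),
    (TaskCondition(E=-10, H=0, T=15), 15.0),  # independent of eye position
])
def test_displacement_vector(cond, expected):
    assert displacement_vector(cond) == pytest.approx(expected)


def test_task_condition_rejects_non_finite():
    with pytest.raises(ValueError):
        TaskCondition(E=np.nan, H=0, T=0)


@pytest.mark.parametrize("t, expected", [
    (-0.2, -10.0),  # delay: he = HE
    (1.0, 20.0),    # offset: he = TE
    (0.5, 5.0),     # 20 - 0.5 * 30
])
def test_desired_trajectory_values(t, expected):
    cond = TaskCondition(E=0, H=-10, T=20)
    assert desired_trajectory(cond, t) == pytest.approx(expected)


def test_hand_position_endpoints_and_domain():
    cond = TaskCondition(E=0, H=-10, T=20)
    assert phenomenological_hand_position(cond, 0.0) == pytest.approx(-10.0)
    assert phenomenological_hand_position(cond, 1.0) == pytest.approx(20.0)
    with pytest.raises(ValueError):
        phenomenological_hand_position(cond, -0.5)


@settings(deadline=None, derandomize=True)
@given(E=positions, H=positions, T=positions, t=movement_times)
def test_visual_and_extrinsic_trajectories_agree(E, H, T, t):
    """h(t) - E must equal he(t): the extrinsic and eye-centered accounts
    describe the same desired movement."""
    cond = TaskCondition(E=E, H=H, T=T)
    he = desired_trajectory(cond, t)
    h = phenomenological_hand_position(cond, t)
    assert h - E == pytest.approx(he, abs=1e-9)


@settings(deadline=None, derandomize=True)
@given(E=positions, H=positions, T=positions, t_delay=st.floats(-2, 0))
def test_trajectory_endpoint_conditions(E, H, T, t_delay):
    cond = TaskCondition(E=E, H=H, T=T)
    # the identities hold to float rounding of the alternative routes
    assert desired_trajectory(cond, t_delay) == pytest.approx(cond.HE,
                                                              abs=1e-9)
    assert desired_trajectory(cond, 1.0) == pytest.approx(cond.TE, abs=1e-9)
    assert cond.TH == pytest.approx(cond.TE - cond.HE, abs=1e-9)


@settings(deadline=None, derandomize=True)
@given(E=positions, H=positions, T=positions)
def test_trajectory_monotone_towards_target(E, H, T):
    """For T > H the desired trajectory is non-decreasing over movement."""
    if T < H:
        T, H = H, T
    cond = TaskCondition(E=E, H=H, T=T)
    ts = np.linspace(0, 1, 21)
    he = np.array([desired_trajectory(cond, t) for t in ts])
    assert np.all(np.diff(he) >= -1e-9)
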