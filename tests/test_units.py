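import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reachframes.kinematics import TaskCondition
from reachframes.tasks import delay_task_conditions
from reachframes.units import (NETWORKS, NoiseModel, UnitSpec, add_noise,
                               alt_unit_response, semilinear_gain,
                               simulate_rates, unit_response)


@pytest.mark.parametrize("x, expected", [(-2.0, 0.0), (0.0, 0.0), (0.5, 0.5)])
def test_semilinear_gain(x, expected):
    assert semilinear_gain(x) == expected


class TestMainNetworkResponses:
    def test_eye_unit_at_full_gain(self):
        unit = UnitSpec("u", "eye", u=0.0, v=0.0, gain_sign=1)
        cond = TaskCondition(E=0, H=15, T=0)  # TE = 0, HE = 15
        assert unit_response(unit, cond, -0.5) == pytest.approx(30.0)

    def test_hand_unit_at_offset_ignores_task(self):
        unit = UnitSpec("u", "hand", u=0.0)
        for cond in (TaskCondition(0, -10, 20), TaskCondition(5, 30, -30)):
            assert unit_response(unit, cond, 1.0) == pytest.approx(30.0)

    def test_hand_unit_pretarget_is_amplitude(self):
        unit = UnitSpec("u", "hand", u=7.5)
        assert unit_response(unit, TaskCondition(0, -10, 20), -1.5) == 30.0

    def test_eye_unit_pretarget_drops_target_tuning(self):
        unit = UnitSpec("u", "eye", u=30.0, v=0.0, gain_sign=1)
        cond = TaskCondition(E=0, H=15, T=0)
        # target factor set to unity: response = A * f(HE / sigma)
        assert unit_response(unit, cond, -1.5) == pytest.approx(30.0)

    def test_unknown_node_errors(self):
        unit = UnitSpec("u", "nonsense", u=0.0)
        with pytest.raises(KeyError):
            unit_response(unit, TaskCondition(0, 0, 0), 0.0)


class TestAlternativeNetworks:
    def test_static_displacement_node(self):
        unit = UnitSpec("u", "hand_static", u=0.0)
        cond = TaskCondition(E=3, H=10, T=10)  # TH = 0
        for t in (-0.5, 0.3, 1.0):
            assert alt_unit_response(unit, cond, t, "rising_phi") == 30.0

    def test_dual_sigmoid_combined_node_during_delay(self):
        unit = UnitSpec("u", "combined", u=0.0, v=0.0, gain_sign=1)
        cond = TaskCondition(E=0, H=15, T=10)  # TE = 10, HE = 15
        # delay: phi = 0 so the Gaussian sits at its onset; psi * HE = 15
        assert alt_unit_response(unit, cond, -0.5, "dual_sigmoid") == \
            pytest.approx(30.0 * 1.0)

    def test_static_hand_variant_keeps_displacement_tuning_at_offset(self):
        unit = UnitSpec("u", "hand_static", u=0.0)
        cond = TaskCondition(E=0, H=-15, T=15)  # TH = 30
        expected = 30.0 * np.exp(-2.0)  # ~4.06: two length scales away
        assert alt_unit_response(unit, cond, 1.0, "static_hand") == \
            pytest.approx(expected)

    def test_variant_without_pretarget_form_errors(self):
        unit = UnitSpec("u", "hand_static", u=0.0)
        with pytest.raises(ValueError, match="pre-target"):
            alt_unit_response(unit, TaskCondition(0, 0, 0), -1.5,
                              "static_hand")

    def test_main_network_rejected(self):
        unit = UnitSpec("u", "eye", u=0.0, v=0.0)
        with pytest.raises(ValueError):
            alt_unit_response(unit, TaskCondition(0, 0, 0), 0.0, "main")


unit_kinds = st.sampled_from([("eye", True), ("hand", False),
                              ("eye_hand", True)])


@settings(deadline=None, derandomize=True, max_examples=50)
@given(kind=unit_kinds, u=st.floats(-45, 45), v=st.floats(-45, 45),
       sign=st.sampled_from([-1, 1]), E=st.floats(-30, 30),
       H=st.floats(-30, 30), T=st.floats(-30, 30), t=st.floats(-2, 1))
def test_noiseless_rates_non_negative(kind, u, v, sign, E, H, T, t):
    node, dual = kind
    unit = UnitSpec("u", node, u=u, v=v if dual else None, gain_sign=sign)
    rate = unit_response(unit, TaskCondition(E, H, T), t)
    assert rate >= 0.0


@settings(deadline=None, derandomize=True, max_examples=30)
@given(u=st.floats(-45, 45), v=st.floats(-45, 45),
       t=st.floats(-1, 0), E=st.floats(-30, 30), H=st.floats(-30, 30),
       T=st.floats(-30, 30))
def test_delay_period_reduces_to_static_displacement(u, v, t, E, H, T):
    """With psi = 1 throughout the delay, dynamic responses equal their
    static-TH counterparts."""
    cond = TaskCondition(E, H, T)
    hand = UnitSpec("h", "hand", u=u)
    hand_static = UnitSpec("h", "hand_static", u=u)
    assert unit_response(hand, cond, t) == pytest.approx(
        alt_unit_response(hand_static, cond, t, "static_hand"))
    dyn = UnitSpec("e", "eye_hand", u=u, v=v, gain_sign=1)
    assert unit_response(dyn, cond, t) == pytest.approx(
        unit_response(dyn, cond, -0.25))


def test_hand_node_degenerate_at_movement_offset(delay_conditions):
    """At t = 1 the dynamic hand-centered response ceases to co-vary with
    the task parameters: zero variance across conditions."""
    units = [UnitSpec(f"h{k}", "hand", u=u) for k, u in
             enumerate((-20.0, 0.0, 20.0))]
    rates = simulate_rates(units, delay_conditions, 1.0)
    assert np.allclose(rates.var(axis=1), 0.0)
    rates_delay = simulate_rates(units, delay_conditions, 0.0)
    assert rates_delay.var(axis=1).max() > 0


def test_gain_sign_symmetry():
    """Swapping the gain slope sign and mirroring HE about v leaves the
    eye-node response unchanged."""
    plus = UnitSpec("p", "eye", u=0.0, v=5.0, gain_sign=1)
    minus = UnitSpec("m", "eye", u=0.0, v=5.0, gain_sign=-1)
    for he in (-20.0, -5.0, 0.0, 10.0, 25.0):
        c_plus = TaskCondition(E=0, H=he, T=0)
        c_minus = TaskCondition(E=0, H=2 * 5.0 - he, T=0)
        assert unit_response(plus, c_plus, 0.0) == pytest.approx(
            unit_response(minus, c_minus, 0.0))


class TestNoise:
    def test_zero_sd_is_identity(self, rng):
        rates = rng.uniform(0, 30, (4, 9))
        out = add_noise(rates, NoiseModel(0.0, seed=1))
        assert np.array_equal(out, rates)

    def test_seeded_noise_is_reproducible(self):
        rates = np.zeros((10, 10))
        noise = NoiseModel(5.0, seed=7)
        assert np.array_equal(add_noise(rates, noise),
                              add_noise(rates, noise))

    def test_noise_is_zero_mean_with_stated_sd(self):
        rates = np.zeros((100, 100))
        out = add_noise(rates, NoiseModel(5.0, seed=3))
        # CLT bound: mean within 4 * sd / sqrt(n) of 0
        assert abs(out.mean()) < 4 * 5.0 / 100.0
        assert out.std() == pytest.approx(5.0, rel=0.05)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(-1.0)
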