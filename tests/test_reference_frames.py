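import numpy as np
import pytest
from scipy import stats

from reachframes.reference_frames import (RefFrameFit, classify_population,
                                          classify_unit, fit_full_model,
                                          fit_submodel, nested_f_test,
                                          reference_frame_distribution,
                                          summarize_distribution)
from reachframes.units import UnitSpec, simulate_rates


def _fit(rss, n=45, w=0.5, w_fixed=None):
    return RefFrameFit(a=30, mu=0, s=15, g=0, c=0, w=w, r2=0.9, rss=rss,
                       n=n, w_fixed=w_fixed)


class TestNestedFTest:
    def test_equal_residuals_give_p_one(self):
        assert nested_f_test(_fit(10.0), _fit(10.0, w_fixed=1)) == 1.0

    def test_doubled_residual_matches_t_distribution_oracle(self):
        """RSS_sub = 2 RSS_full at n = 45 gives F = 39; the tail probability
        must match the identity F(1, d) = t(d)^2."""
        p = nested_f_test(_fit(1.0), _fit(2.0, w_fixed=0))
        oracle = 2.0 * stats.t.sf(np.sqrt(39.0), 39)
        assert p == pytest.approx(oracle, rel=1e-10)
        assert p < 0.01

    def test_degenerate_zero_residuals(self):
        assert nested_f_test(_fit(0.0), _fit(0.0, w_fixed=1)) == 1.0
        assert nested_f_test(_fit(0.0), _fit(5.0, w_fixed=1)) == 0.0

    def test_submodel_better_than_full_signals_failure(self):
        with pytest.raises(RuntimeError):
            nested_f_test(_fit(10.0), _fit(5.0, w_fixed=1))


@pytest.mark.parametrize("p_eye, p_hand, expected", [
    (0.5, 0.001, "eye"),
    (0.001, 0.5, "hand"),
    (0.001, 0.002, "intermediate"),
    (0.5, 0.6, "indeterminate"),
    (0.01, 0.5, "indeterminate"),   # threshold is strict
])
def test_classification_decision_table(p_eye, p_hand, expected):
    assert classify_unit(p_eye, p_hand) == expected


class TestNoiselessFits:
    def test_eye_unit_recovers_eye_frame(self, eye_unit, delay_conditions):
        y = simulate_rates([eye_unit], delay_conditions, 0.0)[0]
        full = fit_full_model(y, delay_conditions)
        assert abs(full.w - 1.0) < 0.05

    def test_hand_unit_recovers_hand_frame(self, hand_unit, delay_conditions):
        y = simulate_rates([hand_unit], delay_conditions, 0.0)[0]
        full = fit_full_model(y, delay_conditions)
        assert abs(full.w) < 0.05

    def test_true_submodel_fits_exactly(self, hand_unit, delay_conditions):
        y = simulate_rates([hand_unit], delay_conditions, 0.0)[0]
        sub_hand = fit_submodel(y, delay_conditions, 0)
        sub_eye = fit_submodel(y, delay_conditions, 1)
        assert sub_hand.rss < 1e-8
        assert sub_eye.rss > sub_hand.rss

    def test_nesting_inequality(self, eye_unit, hand_unit, eye_hand_unit,
                                delay_conditions):
        units = [eye_unit, hand_unit, eye_hand_unit]
        rates = simulate_rates(units, delay_conditions, 0.0)
        for y in rates:
            sub_eye = fit_submodel(y, delay_conditions, 1)
            sub_hand = fit_submodel(y, delay_conditions, 0)
            starts = [np.array([f.a, f.mu, f.s, f.g, f.c, f.w_fixed])
                      for f in (sub_eye, sub_hand)]
            full = fit_full_model(y, delay_conditions, extra_starts=starts)
            tol = 1e-8 * (1 + min(sub_eye.rss, sub_hand.rss))
            assert full.rss <= min(sub_eye.rss, sub_hand.rss) + tol

    def test_eye_and_hand_unit_is_intermediate(self, eye_hand_unit,
                                               delay_conditions):
        y = simulate_rates([eye_hand_unit], delay_conditions, 0.0)[0]
        full = fit_full_model(y, delay_conditions)
        assert 0.0 < full.w < 1.0

    def test_submodel_rejects_bad_w(self, delay_conditions):
        y = np.ones(45)
        with pytest.raises(ValueError):
            fit_submodel(y, delay_conditions, 0.5)

    def test_too_few_conditions(self, delay_conditions):
        with pytest.raises(ValueError):
            fit_full_model(np.ones(3), delay_conditions)


def test_classify_population_noiseless(eye_unit, hand_unit, eye_hand_unit,
                                       delay_conditions):
    units = [eye_unit, hand_unit, eye_hand_unit]
    rates = simulate_rates(units, delay_conditions, 0.0)
    fits = classify_population(rates, delay_conditions, units)
    by_id = fits.set_index("unit_id")["cls"]
    assert by_id["eye_0"] == "eye"
    assert by_id["hand_0"] == "hand"
    assert by_id["eye_hand_0"] == "intermediate"


def test_empty_distribution_warns(delay_conditions):
    table = reference_frame_distribution([], np.empty((0, 45)),
                                         delay_conditions)
    assert table.empty


def test_summarize_distribution(eye_unit, hand_unit, delay_conditions):
    units = [eye_unit, hand_unit]
    rates = simulate_rates(units, delay_conditions, 0.0)
    fits = classify_population(rates, delay_conditions, units)
    summary = summarize_distribution(fits)
    assert summary["per_node"]["eye"]["counts"]["eye"] == 1
    assert summary["per_node"]["hand"]["percentages"]["hand"] == 100.0
    assert sum(summary["w_hist_counts"]) == 2  # both units classified
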