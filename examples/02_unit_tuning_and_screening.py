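"""Simulate single-unit tuning and apply the center-out screen.

Units from the network's internal nodes carry Gaussian target tuning; the
screening task (eye and hand at the center, 9 targets) fits a bounded
four-parameter Gaussian and accepts units whose peak is inside the task
range with spike-variance-explained (r^2 * amplitude) of at least 10.
"""

from reachframes import (UnitSpec, fit_center_out_gaussian, screen_unit,
                         screening_task_conditions, simulate_rates)

conds = screening_task_conditions(15.0)
units = [
    UnitSpec("tuned_center", "hand", u=0.0),
    UnitSpec("tuned_edge", "hand", u=40.0),        # peak outside the range
    UnitSpec("weak_gain", "eye", u=0.0, v=-3.0),   # tiny gain => low SVE
]
rates = simulate_rates(units, conds, t=0.0)

for unit, y in zip(units, rates):
    fit = fit_center_out_gaussian(y, conds.T)
    ok = screen_unit(fit, task_range=(-30.0, 30.0))
    print(f"{unit.unit_id:>12}: a={fit.a:5.1f}  mu={fit.mu:6.1f}  "
          f"s={fit.s:5.1f}  SVE={fit.sve:5.1f}  accepted={ok}")

print()
print("Only the well-tuned central unit passes: the edge unit's peak is")
print("not s/2 inside the range and the weak-gain unit's SVE falls below 10.")
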