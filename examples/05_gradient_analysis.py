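"""Gradient (resultant-vector) analysis across the whole task.

Follows the population resultant of a hybrid hand-centered population
(25% eye, 50% hand, 25% eye-and-hand units) through the pre-target, delay
and movement epochs for the T x H analysis pair.  Directions are halved
doubled-angle resultants, read against the parameter axes: the target axis
T sits at 0 deg, the displacement axis T - H at -45 deg, the hand axis H
at 90 deg.
"""

from reachframes import ExperimentConfig, run_experiment

config = ExperimentConfig(N=10)
result = run_experiment("fig7_hybrid", config=config, seed=0)

samples = result["epoch_samples"]["TxH"]
for epoch in ("pre_target", "go", "offset"):
    s = samples[epoch]
    print(f"{epoch:>11}: direction {s['halved_angle_deg']:7.1f} deg "
          f"(normalized vector [{s['x']:6.3f}, {s['y']:6.3f}])")

print()
print("Before target onset the resultant points along the hand axis; at the")
print("go cue it lies between the displacement (T - H, -45 deg) and target")
print("(T, 0 deg) axes; by movement offset it has rotated onto the target")
print("axis -- the eye-centered frame dominating at the end of the reach.")
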