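"""Compute a desired reach trajectory in visual coordinates.

The internal kinematic model interpolates between the initial hand position
and the reach target: during the delay the desired position sits at the
hand; during movement it advances linearly (in normalized time) to the
target.  All positions are 1D eccentricities in degrees.
"""

import numpy as np

from reachframes import TaskCondition, desired_trajectory, displacement_vector

cond = TaskCondition(E=5.0, H=-10.0, T=20.0)
print(f"task: eye at {cond.E} deg, hand at {cond.H} deg, target at {cond.T} deg")
print(f"eye-centered target TE = {cond.TE} deg, hand HE = {cond.HE} deg")
print(f"displacement vector TH = {displacement_vector(cond)} deg")
print()
print("  t      he(t) [deg, eye-centered]")
for t in np.round(np.arange(-0.5, 1.01, 0.25), 2):
    he = desired_trajectory(cond, t)
    print(f"{t:5.2f}  {he:8.2f}")
print()
print("he equals HE (-15 deg) throughout the delay and reaches TE (15 deg)")
print("at movement offset; intermediate values are the desired trajectory.")
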