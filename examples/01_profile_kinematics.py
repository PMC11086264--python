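"""Closed-form kinematics of one sprint profile.

Builds a profile from MSS (maximal sprinting speed) and MAC (maximal
acceleration), then prints the velocity/acceleration/distance curves and
the predicted timing-gate split times.
"""

import numpy as np

from shortsprint import (
    SprintProfile,
    acceleration_at_time,
    avp_line,
    distance_at_time,
    time_at_distance,
    velocity_at_time,
)

profile = SprintProfile.from_mss_mac(mss=8.0, mac=7.0)
print(f"profile: MSS={profile.mss} m/s  MAC={profile.mac} m/s^2  "
      f"TAU={profile.tau:.4f} s  PMAX={profile.pmax:.3f} W/kg")

print("\n t (s)   v (m/s)   a (m/s^2)   d (m)")
for t in (0.0, 0.5, 1.0, 2.0, 4.0):
    print(f"{t:5.1f}  {float(velocity_at_time(profile, t)):8.3f}"
          f"  {float(acceleration_at_time(profile, t)):9.3f}"
          f"  {float(distance_at_time(profile, t)):7.3f}")

gates = np.array([5.0, 10.0, 20.0, 30.0, 40.0])
times = time_at_distance(profile, gates)
print("\npredicted split times (Lambert-W inversion):")
for d, t in zip(gates, times):
    print(f"  {d:4.0f} m -> {t:.2f} s")

intercept, slope = avp_line(profile)
print(f"\nacceleration-velocity profile: a(v) = {intercept:.2f} "
      f"{slope:+.4f} * v")
print("meaning: the athlete starts at 7 m/s^2 and acceleration fades "
      "linearly to 0 at top speed; split times above are what perfect "
      "timing gates would record.")
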