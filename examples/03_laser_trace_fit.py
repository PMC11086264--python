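"""Fitting the time-shifted velocity model to a laser-gun trace.

Generates a synthetic 1000 Hz velocity trace (truth MSS 9.0 m/s,
TAU 1.2 s, the athlete starting 0.8 s into the recording) with Gaussian
sensor noise, filters out samples below the 0.5 m/s threshold using the
smoothed channel, and fits MSS, TAU and the time correction TC.
"""

from shortsprint import SprintProfile, fit_laser_trace, generate_laser_trace

truth = SprintProfile(mss=9.0, tau=1.2)
trace = generate_laser_trace(
    truth, tc=0.8, sample_rate=1000, target_distance=30,
    noise_sd=0.05, seed=7,
)
print(f"trace: {len(trace)} samples at {trace.sample_rate:.0f} Hz, "
      f"{trace.t[-1]:.2f} s long")

fit = fit_laser_trace(trace, v_threshold=0.5)
p = fit.profile
print(f"fitted: MSS={p.mss:.3f} m/s (true 9.0)   TAU={p.tau:.3f} s "
      f"(true 1.2)   TC={fit.correction.tc:.3f} s (true 0.8)")
print(f"        MAC={p.mac:.3f} m/s^2   PMAX={p.pmax:.2f} W/kg   "
      f"n={fit.n_obs} samples kept of {len(trace)}")
print("\nmeaning: the intercept-like TC parameter absorbs the pre-start "
      "portion of the recording, so the profile parameters are "
      "recovered within a fraction of a percent despite the noise.")
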