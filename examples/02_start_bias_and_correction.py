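"""How a flying start or reaction time distorts gate-based estimates,
and how the correction models repair them.

Three athletes share one true profile (MSS 9.5 m/s, MAC 7 m/s^2) but
start differently: Andrew cleanly, Ben 0.5 m behind the first gate
(flying start), Cole on a gun-started clock (+0.2 s).  Split times are
rounded to the 0.01 s gate precision.
"""

from shortsprint import (
    fit_estimated_fd,
    fit_estimated_tc,
    fit_no_correction,
    generate_triplets,
    triplet_report,
)

splits = generate_triplets()
for name, s in splits.items():
    print(f"{name:7s} splits (s): "
          + "  ".join(f"{t:.2f}" for t in s.times))

print("\nuncorrected fits (No Correction model):")
for name, s in splits.items():
    fit = fit_no_correction(s)
    p = fit.profile
    print(f"  {name:7s} MSS={p.mss:6.2f}  TAU={p.tau:5.2f}  MAC={p.mac:6.2f}")

print("\ncorrected fits:")
ben_fd = fit_estimated_fd(splits["Ben"])
cole_tc = fit_estimated_tc(splits["Cole"])
print(f"  Ben  + estimated flying distance: MSS={ben_fd.profile.mss:.2f}, "
      f"FD={ben_fd.correction.fd:.2f} m (true 0.5 m)")
print(f"  Cole + estimated time correction: MSS={cole_tc.profile.mss:.2f}, "
      f"TC={cole_tc.correction.tc:.2f} s (true reaction time 0.2 s)")

print("\nfull model x athlete matrix:")
df = triplet_report()
cols = ["model", "athlete", "MSS", "TAU", "MAC", "PMAX", "TC", "FD"]
print(df[cols].round(2).to_string(index=False))
print("\nmeaning: uncorrected, Ben's flying start inflates MAC by ~74% "
      "and Cole's reaction time inflates MSS by ~9%; the estimated-TC "
      "and estimated-FD models recover the shared truth to within a "
      "few percent.")
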