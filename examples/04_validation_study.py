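"""Criterion-vs-gates validation on a synthetic cohort.

Simulates a 31-athlete, 2-trial testing session (0.5 m flying start,
0.01 s gate clock), fits a laser-trace criterion per trial, fits the
five timing-gate models, and summarises agreement per parameter: %Bias,
%MAD, %RSE and the minimum detectable change %MDC95.
"""

import numpy as np

from shortsprint import CohortSpec, ValidationConfig, run_validation

report = run_validation(
    spec=CohortSpec(n_athletes=31, n_trials=2),
    config=ValidationConfig(ci=False),  # ci=True adds BCa intervals
    seed=20,
)

sim = report[report["arm"] == "simulated"]
print("simulated-arm agreement (gate models vs laser criterion):\n")
cols = ["model", "parameter", "n", "pct_bias", "pct_mad", "pct_mdc95"]
print(sim[cols].round(2).to_string(index=False))

by_param = sim.groupby("parameter").agg(
    mean_abs_bias=("pct_bias", lambda s: np.mean(np.abs(s))),
    mean_mdc95=("pct_mdc95", "mean"),
).round(2)
print("\naggregated over models:")
print(by_param.to_string())
print("\nmeaning: MSS is the most robust parameter — smallest bias and "
      "smallest detectable-change threshold — while MAC and PMAX are "
      "strongly distorted by an uncorrected flying start; the "
      "estimated-TC/FD models shrink those biases toward zero.")
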