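"""Nine-scenario robustness analysis of a reoptimized plan.

Re-simulates the influence matrices under the canonical protocol --
nominal setup, +/-2 mm rigid shifts along each axis, and +/-3.5 % medium
density -- with the fluence held fixed, and prints the per-structure
envelope of the plan metrics.
"""

import pandas as pd

from letopt import BeamModelParams, build_case, optimize, robustness_suite

case = build_case()
x, _, _ = optimize(case, algorithm="ams")

result = robustness_suite(
    x,
    case.grid,
    case.structures,
    case.spots,
    BeamModelParams(),
    case.config.constraints.prescription_Gy,
)

print(f"{result.n_scenarios} scenarios evaluated: "
      f"{', '.join(result.per_scenario)}\n")
env = pd.concat(
    {"min": result.envelope_min, "max": result.envelope_max}, names=["bound"]
)
cols = ["V95_pct", "D_min_Gy", "D_max_Gy", "cDL_mean_Gy", "cDL30_Gy"]
print(env[cols].round(2).to_string())
print("\nThe [min, max] band is the worst-case spread of each metric under")
print("setup and range uncertainty; the nominal plan lies inside it.  A")
print("narrow V95 band means target coverage is robust to delivery errors.")
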