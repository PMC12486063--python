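"""Reoptimize the baseline plan with AMS feasibility-seeking.

Builds PTV dose-interval constraints ([0.95, 1.07] x 74 Gy) and OAR cDL30
upper constraints from the baseline, runs 200 cyclic AMS sweeps, and
compares the plans.
"""

from letopt import build_case, baseline_fluence, compare_plans, optimize, plan_metrics
from letopt.influence import forward

case = build_case()
rx = case.config.constraints.prescription_Gy
x0 = baseline_fluence(case)
before = plan_metrics(forward(case.influence, x0), case.structures, rx)

x, diag, stacked = optimize(case, algorithm="ams")
after = plan_metrics(forward(case.influence, x), case.structures, rx)

print(f"AMS: {diag['iterations']} iterations, weighted residual "
      f"{diag['residuals'][0]:.3f} -> {diag['residual']:.4f} Gy\n")
print("metrics after reoptimization:\n")
print(after.table.round(2).to_string())

rep = compare_plans(before, after)
row = rep.relative.loc["OAR"]
print("\nrelative change in the OAR (after vs baseline):")
print(f"  cDL mean {100 * row['cDL_mean_Gy']:+.1f} %, "
      f"cDL max {100 * row['cDL_max_Gy']:+.1f} %, "
      f"cDL30 {100 * row['cDL30_Gy']:+.1f} %")
print(f"PTV coverage V95 = {after.structure('PTV')['V95_pct']:.1f} % "
      f"(clinical rule: at least 98 % of the PTV at 95 % of prescription)")
print("The OAR's cDL drops while target coverage is preserved -- the point")
print("of simultaneous dose and LET_d-aware reoptimization.")
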