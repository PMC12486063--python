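"""Forward-calculate a uniform baseline plan and read its volume histograms.

The baseline is a uniform fluence scaled so the PTV mean dose equals the
74 Gy prescription.  Prints DVH/cDLVH summary points per structure,
including the OAR's cDL30 -- the value that becomes its upper constraint
in the reoptimization step.
"""

from letopt import build_case, baseline_fluence, cumulative_vh, plan_metrics, vh_percentile
from letopt.influence import forward

case = build_case()
rx = case.config.constraints.prescription_Gy
x0 = baseline_fluence(case)
fwd = forward(case.influence, x0, dose_floor=case.config.dose_floor_Gy)

metrics = plan_metrics(fwd, case.structures, rx)
print("baseline plan (uniform fluence, PTV mean = prescription):\n")
print(metrics.table.round(2).to_string())

oar_cdl = fwd.cdl[case.structures.flat("OAR")]
vh = cumulative_vh(oar_cdl, "OAR")
cdl30 = vh_percentile(vh, 0.30)
print(f"\nOAR cDL30 = {cdl30:.2f} Gy: 30 % of the OAR receives at least this")
print("cDL; it becomes the per-voxel upper bound [0, cDL30] that the")
print("reoptimization enforces to push high LET x dose out of the OAR.")
print(f"fraction of OAR at or above the bound at baseline: "
      f"{100 * float((oar_cdl >= cdl30).mean()):.0f} % (>= 30 % by construction)")
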