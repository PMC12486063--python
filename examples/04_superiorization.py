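"""Superiorization: feasibility-seeking steered by an objective.

Runs plain AMS and its superiorized version from the same start and
compares the weighted least-squares objective (distance of dose / cDL to
the reference values) and the feasibility residual of the two endpoints.
"""

from letopt import build_case, optimize
from letopt.solvers import objective_chi2

case = build_case()
x_ams, diag_ams, sc = optimize(case, algorithm="ams")
x_sup, diag_sup, _ = optimize(case, algorithm="sup")

chi_ams = objective_chi2(x_ams, sc)
chi_sup = objective_chi2(x_sup, sc)
print("equal iteration budgets (200):")
print(f"  AMS : residual {diag_ams['residual']:.4f} Gy, chi^2 {chi_ams:,.0f}")
print(f"  SA  : residual {diag_sup['residual']:.4f} Gy, chi^2 {chi_sup:,.0f}")
print(f"  accepted perturbation steps: {int((diag_sup['betas'] > 0).sum())}")
print("\nThe bounded negative-gradient perturbations steer iterates toward the")
print("reference dose and cDL values without breaking convergence to the")
print("constraint set: both runs end at essentially the same residual.  On")
print("feasible systems the superiorized endpoint has an equal or lower")
print("objective value than feasibility-seeking alone (the package's test")
print("suite verifies this statistically on planted-feasible instances); on")
print("this deliberately tight phantom the two endpoints nearly coincide.")
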