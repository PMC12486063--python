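# Methods

## Model overview

The package treats spot-scanning proton plan reoptimization as a voxel-wise
interval feasibility problem over nonnegative beamlet fluences, with an
optional superiorization layer.  Three linear operators drive everything:

* the **dose influence matrix** `D` (Gy per primary, voxels × beamlets);
* the **LET_d numerator matrix** `N` with `N_ij = LET_d,ij · D_ij`
  (Gy·keV/μm per primary), so that the dose-averaged LET of any fluence
  `x` is `LET_d(x) = (N x) / (D x)` voxel-wise;
* the **cDL operator** `c · N` with `c = 0.04 μm/keV`, giving
  `cDL(x) = c · D(x) · LET_d(x) = c · (N x)` in Gy.

Dose-averaged LET is a ratio and therefore not additive across beamlets or
fields; its numerator and denominator are.  Storing the numerator
separately and adopting the standard simplification *denominator ≈ total
dose* makes cDL exactly linear in `x`; the identity
`c·D(x)·LET_d(x) = c·(N x)` then holds to machine precision, which the test
suite asserts at `1e-12` relative.  An exact two-component denominator can
be carried alongside (`letd_denominator`) for reporting, but the forward
model and all constraints use the linear form.  Voxels with dose at or
below a floor (default `1e-6` × prescription) report LET_d = 0; the floor
suppresses noise-dominated LET in essentially unirradiated voxels.

## Constraints

Targets are constrained in dose space: every PTV voxel receives the
interval `[0.95, 1.07] × prescription`.  The lower fraction implements, as
a per-voxel sufficient condition, the clinical coverage rule that at least
98 % of the PTV receives 95 % of the prescribed dose; the rule itself is
non-convex in DVH space and is checked post hoc by the evaluation module.
The upper fraction (1.07) is a homogeneity choice exposed in the
configuration; clinical practice varies around 105–110 %.

OARs are constrained in cDL space.  For each OAR the cumulative cDL volume
histogram of a baseline forward calculation is built and its **cDL30** —
the cDL received by 30 % of the structure — becomes the per-voxel upper
bound `[0, cDL30]`.  By the step-percentile definition at least 30 % of
the structure violates (or meets with equality) the new bound at the
baseline, so the constraint actively reduces high LET·dose.  Percentiles
use the step convention: the largest value `v` with `V(v) ≥ fraction`,
i.e. the `⌈fraction·n⌉`-th largest voxel value, with no interpolation —
integer-exact and platform-reproducible.

Voxels belonging to both a target and an OAR follow the target's dose row
only (target priority; the OAR percentile is still computed over the full
structure).  Constraint rows whose influence row is entirely zero are
dropped with a warning at assembly: no fluence can affect them and the
projection onto such a row is undefined.

## Solvers

**AMS feasibility-seeking.**  Each interval is a slab
`L_i ≤ ⟨a_i, x⟩ ≤ U_i`; the Euclidean projection displacement is
`d_i = ((bound − ⟨a_i,x⟩)/‖a_i‖²) a_i` for a violated bound, zero
otherwise.  Two iteration schemes are provided:

* `mode="cyclic"` (default): one iteration sweeps all rows in ascending
  weight order, applying the relaxed projection row by row with a
  nonnegativity clamp after each.  Sweeping low-priority (OAR) rows first
  and target rows last means the target bounds are enforced exactly at the
  end of every sweep — the classical cyclic relaxation method, and the
  natural choice on a CPU where projections execute serially anyway.
* `mode="simultaneous"`: the Cimmino-type averaged step
  `x ← clamp₊(x + λ Σ_i w̃_i d_i)` with weights normalised over all rows,
  suited to massively parallel hardware.  It is Fejér monotone for
  `λ ∈ (0, 2)` (asserted by the tests for λ ∈ {0.5, 1.0, 1.9}) but moves
  only ~1/m of a projection per iteration on m rows; at a 200-iteration
  budget on a few hundred rows this is an order of magnitude short of
  convergence, which is why it is not the default.

Relaxation is restricted to `0 < λ ≤ 2` (constructor-enforced).
Nonnegativity of the fluence is maintained by clamping — the orthant is an
additional convex set containing every physical solution, so the clamp
preserves Fejér monotonicity.  Iteration stops at the cap (default 200) or
when the weighted residual `√(Σ w̃_i viol_i²)` (Gy) falls to the tolerance
(default 0, i.e. exact feasibility).  Violations are tested with a
`1e-12`-relative guard so boundary equality does not oscillate.

**Superiorization.**  Each outer iteration (a) takes `N` perturbation
steps `x ← clamp₊(x + β v)` with `v = −∇χ²/‖∇χ²‖` and `β = α^s · scale`,
where `s` increments on *every* trial and a step is accepted only if it
does not increase χ²; (b) multiplies the objective weights by `η`
(cumulatively `η^k`; configurable to decay all terms or only the OAR
terms); (c) performs one feasibility-seeking iteration.  Because
`Σ_s α^s = α/(1−α)` converges, total perturbations are bounded by
`α/(1−α) · scale` and the perturbed iterates retain the feasibility
behaviour of the unperturbed ones (perturbation resilience; tested as a
10× residual bound).  The scale is `max(1, ‖x₀‖_∞)`, captured at entry, so
steps are commensurate with the fluence magnitude.  χ² uses the reference
values `D̂_i` (the prescription, for target rows) and `cD̂L_i` (the cDL30
bound, for OAR rows); the reported χ² trace uses the *original* weights so
superiorized and plain runs are directly comparable.  In the
vanishing-perturbation limit (α → 0) the trajectory reduces to plain
feasibility-seeking (tested at α = 1e-6, agreement 1e-6).

## The synthetic phantom and beam model

The phantom module replaces a Monte Carlo transport engine with an
analytic stand-in that reproduces the *structure* the optimizer depends
on, not clinical beam data.  Its parameters are synthetic throughout.

* **Range–energy:** Bragg–Kleeman `R0(E) = a·E^p` with `a = 0.022` mm,
  `p = 1.77` (protons in water to within a few percent); valid window
  30–250 MeV, energies outside raise.
* **Depth–dose:** single-peaked; a plateau rising from
  `entrance_to_peak = 0.35` of the peak (exact at depth 0 by
  renormalising the proximal Gaussian) into a Gaussian peak of width
  6 mm at `R0`, Gaussian distal falloff, identically zero beyond
  `R0 + 4` widths.  The 6 mm width is deliberately at the broad end of
  the physical range-straggling scale: it smooths the spread-out Bragg
  peak so that a uniform-fluence plan over the layer stack is a sensible
  baseline.
* **LET_d depth curve:** piecewise-linear, monotone non-decreasing from
  2 keV/μm at the surface to 10 keV/μm at the distal dose edge, with 80 %
  of the rise in the last ~3 peak widths — the end-of-range elevation that
  creates the clinical problem.  The influence simulation sets
  `N_ij = LET_d(depth) · D_ij` exactly, so numerator/denominator
  additivity holds by construction.
* **Lateral profile:** Gaussian with `σ(d) = 7 mm + 0.02·d` — again the
  broad end of clinical pencil-beam widths, chosen so a 10.5 mm spot
  lattice gives a flat lateral dose inside the footprint.
* **Geometry:** fields are axis-aligned (gantry multiples of 90°, couch
  0); the default plan uses two opposed fields along x.  Spot placement
  covers the target's depth extent with 5 energy layers extended 5 mm
  proximally and distally, and a lateral lattice extended 9 mm beyond the
  target footprint — the margins every clinical system applies so that
  edge voxels are interior to the spot coverage.  For the default 20³
  phantom this yields 120 spots.
* **Default structures:** a 9 mm spherical PTV at the grid centre and a
  12 × 54 × 54 mm box OAR abutting its +x pole, i.e. on the beam axis:
  the distal edge of one field and the entrance channel of the opposed
  field.  This is the configuration in which LET_d-aware planning has
  leverage — the optimizer can shift load between the field that *stops*
  at the OAR (high LET_d) and the field that merely *passes through* it
  (entrance LET_d ≈ 2 keV/μm) — and it makes the constraint system
  feasible by construction rather than contradictory.
* **Sparsity floor:** entries below `1e-4` of a column's maximum are
  dropped; on the default phantom this retains > 99.5 % of the total dose.
* **Density scenarios:** a density factor ρ rescales effective depth as
  `d_eff = d/ρ`, so ρ = 0.965 pulls the Bragg peak proximally; the ±3.5 %
  robustness scenarios use this first-order water-equivalent-path-length
  model.  Rigid setup error is modelled by shifting the patient grid
  relative to the beams, avoiding resampling artifacts.

What the generator does **not** emulate: nuclear interactions and
secondary-particle halos, tissue heterogeneity and CT calibration, spot
delivery order and machine limits, statistical MC noise, oblique beam
angles.  Passing tests therefore demonstrate the correctness of the
optimization machinery and the qualitative clinical behaviour (OAR cDL
reduction at preserved coverage, ~20 % on the default phantom), not
dosimetric accuracy for any real beam line.

## Evaluation

Per-structure metrics: V95 (percent of voxels at ≥ 95 % of prescription),
dose min/mean/max, cDL min/mean/max and cDL30.  V95 comparisons allow
`1e-9` relative slack at the threshold: projection iterates place active
voxels *exactly on* the coverage bound, and a strict floating-point `≥`
would miscount boundary-equal voxels by rounding; the slack is
rounding-scale (∼7e-8 Gy at 74 Gy) and cannot hide a genuine shortfall.
Plan comparison reports absolute and relative deltas, with relative deltas
flagged (NaN) where the baseline metric is zero.  The robustness protocol
evaluates a fixed fluence under nine scenarios — nominal, ±2 mm shifts
along each axis, ±3.5 % density — re-simulating the influence per scenario
and reporting the per-metric min/max envelope; the nominal plan lies
inside the envelope by construction.

## Numerical choices and degenerate inputs

* Voxel indexing is 0-based, x-fastest (`idx = i + nx(j + ny k)`),
  declared in the sparse file header; the MetaImage writer uses the same
  ordering, so flat vectors round-trip exactly.
* The sparse influence file stores values as C99 hex floats, making the
  write→read round trip bit-exact by construction.
* Empty structures, all-zero influence matrices, zero constraint rows,
  out-of-domain parameters (λ, α, η, fractions, c) and negative fluences
  are rejected with descriptive errors rather than propagated.
* All solver math is deterministic given the starting fluence; the only
  randomness in the package is the optional structure-centre jitter in
  the phantom generator, driven by an explicit integer seed.

## Problem sizes

Default studies run on a 20³ grid (3 mm, 8000 voxels) with ~120 beamlets
and a few hundred constraint rows; solver toys use 50 voxels × 10
beamlets with planted feasible points.  At these sizes the full pipeline —
simulation, constraint construction, 200 iterations of either solver, and
the nine-scenario robustness suite — completes in seconds, which keeps the
test suite fast while exercising every code path at realistic sparsity.

## Known limitations

* Cyclic sweeps are inherently serial; a GPU port would use the
  simultaneous mode with many more iterations.
* Per-voxel bounds are a sufficient surrogate for DVH criteria; true
  percentile (DVH) constraints are non-convex and out of scope.
* The OAR cDL30 rule always bites (30 % of the structure starts at or
  above the bound), so on geometries without a low-LET escape route the
  constraint system can be genuinely inconsistent; the solvers then
  converge to a weighted compromise and report the residual plateau
  rather than failing.
* Beam angles are restricted to axis-aligned fields; arbitrary gantry and
  couch angles would need a ray-tracing rotation layer.
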