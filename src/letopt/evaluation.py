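"""Plan evaluation: DVH-style metrics, plan comparison, robustness protocol.

Metrics per structure: V95 (percent of the structure receiving at least
95 % of the prescription), dose min/mean/max, cDL min/mean/max and cDL30.
The robustness protocol re-evaluates a *fixed* fluence vector under nine
scenarios -- the nominal setup, rigid patient shifts of +/-2 mm along each
axis, and medium-density factors of 0.965 / 1.035 -- re-simulating the
influence matrices per scenario and reporting the per-metric min/max
envelope across scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .constraints import cumulative_vh, vh_percentile
from .grid import StructureSet, VoxelGrid
from .influence import DEFAULT_C, ForwardResult, forward
from .phantom import BeamModelParams, SpotList, simulate_influence

__all__ = [
    "PlanMetrics",
    "plan_metrics",
    "DifferenceReport",
    "compare_plans",
    "relative_difference_image",
    "RobustnessScenario",
    "canonical_scenarios",
    "RobustnessResult",
    "robustness_suite",
]

METRIC_COLUMNS = [
    "V95_pct",
    "D_min_Gy",
    "D_mean_Gy",
    "D_max_Gy",
    "cDL_min_Gy",
    "cDL_mean_Gy",
    "cDL_max_Gy",
    "cDL30_Gy",
]


@dataclass(frozen=True)
class PlanMetrics:
    """Per-structure dose and cDL statistics (rows: structures)."""

    table: pd.DataFrame
    prescription_Gy: float

    def structure(self, name: str) -> pd.Series:
        return self.table.loc[name]


def plan_metrics(
    fwd: ForwardResult,
    structures: StructureSet,
    prescription_Gy: float,
    v95_fraction: float = 0.95,
    cdl_fraction: float = 0.30,
) -> PlanMetrics:
    """Compute per-structure metrics from forward images.

    V95 counts voxels with dose >= ``v95_fraction * prescription``.
    Boundary equality counts as covered: the comparison allows 1e-9
    relative slack so a voxel that a projection step placed exactly on the
    coverage threshold is not dropped by floating-point rounding.  cDL30
    uses the step-percentile convention of the constraints module.
    """
    if fwd.dose.size != structures.grid.n_voxels:
        raise ValueError(
            f"forward result has {fwd.dose.size} voxels, grid has {structures.grid.n_voxels}"
        )
    rows = {}
    threshold = v95_fraction * prescription_Gy * (1.0 - 1e-9)
    for name in structures.names:
        flat = structures.flat(name)
        dose = fwd.dose[flat]
        cdl = fwd.cdl[flat]
        rows[name] = [
            100.0 * float(np.count_nonzero(dose >= threshold)) / dose.size,
            float(dose.min()),
            float(dose.mean()),
            float(dose.max()),
            float(cdl.min()),
            float(cdl.mean()),
            float(cdl.max()),
            vh_percentile(cumulative_vh(cdl, name), cdl_fraction),
        ]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=METRIC_COLUMNS)
    table.index.name = "structure"
    return PlanMetrics(table=table, prescription_Gy=prescription_Gy)


@dataclass(frozen=True)
class DifferenceReport:
    """Per-structure metric deltas between two plans.

    ``relative`` is ``(after - before) / before``; entries where the
    "before" value is zero are flagged as NaN (not computed) rather than
    reported as infinities.
    """

    absolute: pd.DataFrame
    relative: pd.DataFrame


def compare_plans(before: PlanMetrics, after: PlanMetrics) -> DifferenceReport:
    if set(before.table.index) != set(after.table.index):
        raise ValueError(
            f"structure sets differ: {sorted(before.table.index)} vs {sorted(after.table.index)}"
        )
    b = before.table
    a = after.table.loc[b.index]
    absolute = a - b
    relative = absolute.where(b != 0) / b.where(b != 0)
    return DifferenceReport(absolute=absolute, relative=relative)


def relative_difference_image(after, before, floor: float = 0.0) -> np.ndarray:
    """Voxel-wise ``(after - before) / before`` with a denominator guard.

    The denominator is clipped from below at ``floor`` (typically the
    LET_d dose floor), so near-zero baseline voxels do not blow up the
    map; voxels whose clipped denominator is still zero report 0.
    """
    after = np.asarray(after, dtype=float)
    before = np.asarray(before, dtype=float)
    if after.shape != before.shape:
        raise ValueError(f"image shapes differ: {after.shape} vs {before.shape}")
    denom = np.maximum(before, floor)
    out = np.zeros_like(after)
    np.divide(after - before, denom, out=out, where=denom > 0)
    return out


@dataclass(frozen=True)
class RobustnessScenario:
    """One perturbed-delivery scenario: a rigid shift and/or density factor."""

    label: str
    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    density: float = 1.0

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density factor must be > 0")


def canonical_scenarios(shift_mm: float = 2.0, density_pct: float = 3.5) -> list[RobustnessScenario]:
    """The nine-scenario protocol: nominal, +/-shift per axis, +/-density."""
    scenarios = [RobustnessScenario("nominal")]
    for axis, tag in enumerate("xyz"):
        for sign in (+1, -1):
            shift = [0.0, 0.0, 0.0]
            shift[axis] = sign * shift_mm
            scenarios.append(
                RobustnessScenario(f"shift_{tag}{sign * shift_mm:+g}mm", tuple(shift))
            )
    for sign in (+1, -1):
        f = 1.0 + sign * density_pct / 100.0
        scenarios.append(
            RobustnessScenario(f"density{sign * density_pct:+g}pct", density=f)
        )
    return scenarios


@dataclass(frozen=True)
class RobustnessResult:
    """Per-scenario metrics plus the min/max envelope across scenarios."""

    per_scenario: dict[str, PlanMetrics]
    envelope_min: pd.DataFrame
    envelope_max: pd.DataFrame

    @property
    def n_scenarios(self) -> int:
        return len(self.per_scenario)


def robustness_suite(
    x,
    grid: VoxelGrid,
    structures: StructureSet,
    spots: SpotList,
    params: BeamModelParams,
    prescription_Gy: float,
    scenarios: list[RobustnessScenario] | None = None,
    c: float = DEFAULT_C,
    dose_floor: float = 0.0,
) -> RobustnessResult:
    """Evaluate a fixed fluence vector under each scenario.

    The influence matrices are re-simulated per scenario (patient shift and
    density factor), the forward images recomputed with the *same* fluence
    ``x``, and the per-structure metrics collected.  The envelope is the
    elementwise min/max over scenarios; the nominal plan lies inside it by
    construction when the nominal scenario is in the list.
    """
    scenarios = scenarios if scenarios is not None else canonical_scenarios()
    per_scenario: dict[str, PlanMetrics] = {}
    for scen in scenarios:
        scen_params = replace(params, density_scale=params.density_scale * scen.density)
        try:
            infl = simulate_influence(
                grid, spots, scen_params, patient_shift_mm=scen.shift_mm
            )
        except ValueError as exc:
            raise ValueError(f"scenario {scen.label!r}: {exc}") from None
        fwd = forward(infl, x, c=c, dose_floor=dose_floor)
        per_scenario[scen.label] = plan_metrics(fwd, structures, prescription_Gy)
    stacked = pd.concat([m.table for m in per_scenario.values()])
    order = next(iter(per_scenario.values())).table.index
    env_min = stacked.groupby(level=0).min().reindex(order)
    env_max = stacked.groupby(level=0).max().reindex(order)
    return RobustnessResult(per_scenario=per_scenario, envelope_min=env_min, envelope_max=env_max)
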