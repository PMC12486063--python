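"""End-to-end convenience workflow on synthetic phantoms.

Chains the pieces the way a planning study uses them: build a phantom,
lay out opposed fields over the target, simulate influence matrices,
normalise a uniform baseline fluence to the prescription, derive the
constraint set (PTV dose intervals + OAR cDL30 upper bounds from the
baseline forward calculation), and run the chosen solver.  The CLI, the
examples and the acceptance script all call these functions; nothing here
adds behaviour beyond composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .constraints import (
    ConstraintSet,
    StackedConstraints,
    build_oar_cdl_constraints,
    build_ptv_constraints,
)
from .grid import StructureSet, VoxelGrid
from .influence import ForwardResult, InfluenceMatrix, forward
from .phantom import (
    SpotList,
    default_layout,
    make_phantom,
    opposed_fields_spots,
    simulate_influence,
)
from .solvers import feasibility_seek, superiorize

__all__ = ["Case", "build_case", "baseline_fluence", "build_constraints", "optimize"]


@dataclass
class Case:
    """A fully prepared synthetic case ready for optimization."""

    config: RunConfig
    grid: VoxelGrid
    structures: StructureSet
    spots: SpotList
    influence: InfluenceMatrix

    @property
    def ptv_name(self) -> str:
        return self.structures.targets()[0]

    def ptv_flat(self) -> np.ndarray:
        return self.structures.flat(self.ptv_name)


def build_case(config: RunConfig | None = None) -> Case:
    """Phantom + spot list + influence matrices from one configuration."""
    config = config or RunConfig()
    ph = config.phantom
    layout = ph.layout if ph.layout is not None else default_layout(ph.ptv_radius_mm)
    grid, structures = make_phantom(ph.dims, ph.spacing, layout, seed=ph.seed)
    target = structures.targets()[0]
    spots = opposed_fields_spots(
        grid,
        structures.mask(target),
        config.beam,
        n_energy_layers=ph.n_energy_layers,
        lateral_spacing_mm=ph.lateral_spacing_mm,
    )
    infl = simulate_influence(grid, spots, config.beam)
    return Case(config, grid, structures, spots, infl)


def baseline_fluence(case: Case) -> np.ndarray:
    """Uniform fluence scaled so the PTV mean dose equals the prescription."""
    x = np.ones(case.influence.n_beamlets)
    mean_dose = float((case.influence.dose @ x)[case.ptv_flat()].mean())
    if mean_dose <= 0:
        raise ValueError("baseline plan deposits no dose in the target")
    return x * (case.config.constraints.prescription_Gy / mean_dose)


def build_constraints(case: Case, baseline: ForwardResult) -> tuple[ConstraintSet, StackedConstraints]:
    """PTV dose intervals plus OAR cDL30 upper bounds from the baseline."""
    cc = case.config.constraints
    ptv_flat = case.ptv_flat()
    cs = build_ptv_constraints(
        ptv_flat,
        cc.prescription_Gy,
        lower_frac=cc.ptv_lower_frac,
        upper_frac=cc.ptv_upper_frac,
        weight=cc.ptv_weight,
        structure=case.ptv_name,
    )
    oar_masks = {name: case.structures.flat(name) for name in case.structures.oars()}
    if oar_masks:
        cs = cs + build_oar_cdl_constraints(
            baseline,
            oar_masks,
            fraction=cc.oar_fraction,
            weight_map={name: cc.oar_weight for name in oar_masks},
            exclude_mask=ptv_flat,
        )
    return cs, cs.assemble(case.influence, c=case.config.c)


def optimize(case: Case, algorithm: str = "ams", x0: np.ndarray | None = None):
    """Run the full reoptimization; returns ``(x, diagnostics, stacked)``."""
    x0 = baseline_fluence(case) if x0 is None else np.asarray(x0, dtype=float)
    baseline = forward(case.influence, x0, c=case.config.c, dose_floor=case.config.dose_floor_Gy)
    _, stacked = build_constraints(case, baseline)
    if algorithm == "ams":
        x, diag = feasibility_seek(x0, stacked, case.config.ams)
    elif algorithm in ("sup", "superiorization"):
        x, diag = superiorize(x0, stacked, case.config.ams, case.config.superiorization)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected 'ams' or 'sup'")
    return x, diag, stacked
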