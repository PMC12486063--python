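"""Volume histograms and per-voxel interval constraints.

Targets are constrained in dose space and organs at risk in cDL space:

* every PTV voxel gets a dose interval ``[lower_frac, upper_frac] * Rx``
  (defaults 0.95 / 1.07).  The per-voxel lower bound at 95 % of the
  prescription is a sufficient condition for the clinical DVH rule that at
  least 98 % of the PTV receives 95 % of the prescribed dose; the DVH rule
  itself is non-convex and is checked post hoc by the evaluation module.
* every OAR voxel gets a cDL upper bound equal to the structure's cDL30 --
  the cDL value received by 30 % of the structure volume -- extracted from
  the cumulative cDL volume histogram of a baseline forward calculation.
  By construction at least 30 % of the structure is at or above the bound
  at the baseline fluence, so the constraint actively pushes cDL down.

Percentile extraction uses the step convention (largest value ``v`` with
``V(v) >= fraction``, no interpolation), which is integer-exact on small
structures and reproducible across platforms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .influence import DEFAULT_C, ForwardResult, InfluenceMatrix

__all__ = [
    "VolumeHistogram",
    "cumulative_vh",
    "vh_percentile",
    "ConstraintSet",
    "StackedConstraints",
    "build_ptv_constraints",
    "build_oar_cdl_constraints",
]

SPACE_DOSE = "dose"
SPACE_CDL = "cdl"


@dataclass(frozen=True)
class VolumeHistogram:
    """Cumulative volume histogram: V(v) = fraction of voxels with value >= v.

    Keeps the raw per-voxel values (sorted ascending) so percentile queries
    are exact; ``curve`` renders the non-increasing cumulative curve on a
    value axis for plotting or export.
    """

    values: np.ndarray
    structure: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.sort(np.asarray(self.values, dtype=float)))

    @property
    def n(self) -> int:
        return self.values.size

    def volume_at(self, v) -> np.ndarray:
        """Volume fraction receiving at least ``v``."""
        idx = np.searchsorted(self.values, np.asarray(v, dtype=float), side="left")
        out = (self.n - idx) / self.n
        return out if out.ndim else float(out)

    def curve(self, bins: int = 256) -> tuple[np.ndarray, np.ndarray]:
        axis = np.linspace(0.0, self.values[-1] if self.n else 1.0, bins)
        return axis, np.asarray(self.volume_at(axis))


def cumulative_vh(values_in_structure, structure: str = "") -> VolumeHistogram:
    """Cumulative VH of the values inside one structure.

    Raises ``ValueError`` on an empty structure.
    """
    values = np.asarray(values_in_structure, dtype=float).ravel()
    if values.size == 0:
        raise ValueError(f"structure {structure!r} is empty; cannot build a volume histogram")
    return VolumeHistogram(values, structure)


def vh_percentile(vh: VolumeHistogram, volume_fraction: float) -> float:
    """Value received by at least ``volume_fraction`` of the structure.

    Step convention: the largest value ``v`` with ``V(v) >= fraction``.
    With ``n`` voxels this is the ``ceil(fraction * n)``-th largest value.
    ``volume_fraction`` must lie strictly inside (0, 1).
    """
    if not 0.0 < volume_fraction < 1.0:
        raise ValueError(f"volume_fraction must be in (0, 1), got {volume_fraction}")
    k = math.ceil(volume_fraction * vh.n)
    return float(vh.values[vh.n - k])


@dataclass
class ConstraintSet:
    """Per-voxel interval constraints, in dose or cDL space.

    Arrays are aligned row-wise: ``voxel`` (0-based linear index), ``space``
    (``"dose"`` or ``"cdl"``), ``lower``/``upper`` bounds (Gy), ``weight``
    (> 0), ``reference`` (the objective's target value: the prescription
    for PTV rows, the cDL30 bound for OAR rows), ``structure`` name.
    """

    voxel: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    space: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    lower: np.ndarray = field(default_factory=lambda: np.empty(0))
    upper: np.ndarray = field(default_factory=lambda: np.empty(0))
    weight: np.ndarray = field(default_factory=lambda: np.empty(0))
    reference: np.ndarray = field(default_factory=lambda: np.empty(0))
    structure: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))

    def __post_init__(self) -> None:
        n = len(self.voxel)
        for name in ("space", "lower", "upper", "weight", "reference", "structure"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"constraint field {name!r} length mismatch")
        if n:
            if np.any(self.lower > self.upper):
                raise ValueError("constraint has lower bound above upper bound")
            if np.any(self.weight <= 0):
                raise ValueError("constraint weights must be > 0")

    def __len__(self) -> int:
        return len(self.voxel)

    @staticmethod
    def concat(sets: list["ConstraintSet"]) -> "ConstraintSet":
        sets = [s for s in sets if len(s)]
        if not sets:
            return ConstraintSet()
        return ConstraintSet(
            voxel=np.concatenate([s.voxel for s in sets]),
            space=np.concatenate([s.space for s in sets]),
            lower=np.concatenate([s.lower for s in sets]),
            upper=np.concatenate([s.upper for s in sets]),
            weight=np.concatenate([s.weight for s in sets]),
            reference=np.concatenate([s.reference for s in sets]),
            structure=np.concatenate([s.structure for s in sets]),
        )

    def __add__(self, other: "ConstraintSet") -> "ConstraintSet":
        return ConstraintSet.concat([self, other])

    def assemble(self, infl: InfluenceMatrix, c: float = DEFAULT_C) -> "StackedConstraints":
        """Materialise the constraint rows against an influence matrix.

        Dose rows are rows of ``D``; cDL rows are rows of ``c * N``.  Rows
        whose influence row is entirely zero (the voxel receives nothing
        from any beamlet) are dropped with a warning: no fluence can affect
        them and a projection onto them is undefined.
        """
        if len(self) == 0:
            raise ValueError("empty constraint set")
        is_dose = self.space == SPACE_DOSE
        order = np.argsort(~is_dose, kind="stable")  # dose rows first
        vox = self.voxel[order]
        is_dose = is_dose[order]
        blocks = []
        if is_dose.any():
            blocks.append(infl.dose[vox[is_dose]])
        if (~is_dose).any():
            blocks.append(c * infl.letd_numerator[vox[~is_dose]])
        a = sparse.vstack(blocks, format="csr")
        row_norm_sq = np.asarray(a.multiply(a).sum(axis=1)).ravel()
        keep = row_norm_sq > 0
        if not keep.all():
            dropped = np.asarray(self.structure[order])[~keep]
            warnings.warn(
                f"dropped {int((~keep).sum())} constraint rows on voxels with no "
                f"beamlet coverage (structures: {sorted(set(dropped))})",
                stacklevel=2,
            )
        return StackedConstraints(
            A=a[keep],
            lower=self.lower[order][keep],
            upper=self.upper[order][keep],
            weight=self.weight[order][keep].astype(float),
            reference=self.reference[order][keep].astype(float),
            space=self.space[order][keep],
            voxel=vox[keep],
            structure=self.structure[order][keep],
            row_norm_sq=row_norm_sq[keep],
        )


@dataclass
class StackedConstraints:
    """Constraint rows assembled into one sparse system ``L <= A x <= U``."""

    A: sparse.csr_matrix
    lower: np.ndarray
    upper: np.ndarray
    weight: np.ndarray
    reference: np.ndarray
    space: np.ndarray
    voxel: np.ndarray
    structure: np.ndarray
    row_norm_sq: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.A.shape[0]

    @property
    def n_beamlets(self) -> int:
        return self.A.shape[1]


def build_ptv_constraints(
    ptv_mask,
    prescription_Gy: float,
    lower_frac: float = 0.95,
    upper_frac: float = 1.07,
    weight: float = 1.0,
    structure: str = "PTV",
) -> ConstraintSet:
    """Dose-space interval rows for every PTV voxel.

    ``ptv_mask`` is a flat boolean mask (linear-index order) or an integer
    index array.  Each voxel gets the interval
    ``[lower_frac, upper_frac] * prescription`` with reference value equal
    to the prescription.
    """
    if prescription_Gy <= 0:
        raise ValueError("prescription must be > 0")
    if not 0 < lower_frac <= 1 <= upper_frac:
        raise ValueError(f"need 0 < lower_frac <= 1 <= upper_frac, got {lower_frac}, {upper_frac}")
    mask = np.asarray(ptv_mask)
    vox = np.flatnonzero(mask) if mask.dtype == bool else mask.astype(int)
    if vox.size == 0:
        raise ValueError("PTV mask is empty")
    n = vox.size
    return ConstraintSet(
        voxel=vox,
        space=np.full(n, SPACE_DOSE, dtype=object),
        lower=np.full(n, lower_frac * prescription_Gy),
        upper=np.full(n, upper_frac * prescription_Gy),
        weight=np.full(n, float(weight)),
        reference=np.full(n, float(prescription_Gy)),
        structure=np.full(n, structure, dtype=object),
    )


def build_oar_cdl_constraints(
    baseline_forward: ForwardResult,
    oar_masks: dict[str, np.ndarray],
    fraction: float = 0.30,
    weight_map: dict[str, float] | None = None,
    exclude_mask=None,
) -> ConstraintSet:
    """cDL-space upper-bound rows for every OAR voxel.

    For each OAR, the cDL volume histogram of the baseline forward
    calculation is built, the cDL30 (by default) is extracted with the step
    percentile convention, and every OAR voxel receives the interval
    ``[0, cDL30]`` with reference value cDL30.  An OAR with zero baseline
    dose everywhere is skipped with a warning -- there is nothing to
    reduce.  Voxels in ``exclude_mask`` (typically the PTV, which keeps
    target priority) get no cDL row, but the percentile is still computed
    over the full structure.
    """
    weight_map = weight_map or {}
    sets = []
    exclude = None if exclude_mask is None else np.asarray(exclude_mask, dtype=bool)
    for name in sorted(oar_masks):
        flat = np.asarray(oar_masks[name], dtype=bool)
        cdl_vals = baseline_forward.cdl[flat]
        if cdl_vals.size == 0:
            raise ValueError(f"OAR {name!r} mask is empty")
        if cdl_vals.max() <= 0:
            warnings.warn(
                f"OAR {name!r} receives no baseline dose; cDL constraint skipped",
                stacklevel=2,
            )
            continue
        bound = vh_percentile(cumulative_vh(cdl_vals, name), fraction)
        vox = np.flatnonzero(flat if exclude is None else (flat & ~exclude))
        if vox.size == 0:
            warnings.warn(
                f"OAR {name!r} fully excluded by target priority; cDL constraint skipped",
                stacklevel=2,
            )
            continue
        n = vox.size
        sets.append(
            ConstraintSet(
                voxel=vox,
                space=np.full(n, SPACE_CDL, dtype=object),
                lower=np.zeros(n),
                upper=np.full(n, bound),
                weight=np.full(n, float(weight_map.get(name, 1.0))),
                reference=np.full(n, bound),
                structure=np.full(n, name, dtype=object),
            )
        )
    return ConstraintSet.concat(sets)
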