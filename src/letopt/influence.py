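"""Sparse influence matrices and the linear forward model.

An influence matrix maps per-beamlet unit fluence to a per-voxel deposited
quantity.  The dose component ``D_ij`` (Gy per primary) is a single sparse
matrix; dose-averaged LET needs two components because LET_d itself is not
additive across beamlets -- only the numerator and denominator of

    LET_d(x)_i = (N x)_i / (D x)_i

are.  We store the numerator ``N_ij`` (Gy.keV/um per primary) and adopt the
standard simplification that the denominator equals the total dose, which
makes the composite quantity

    cDL(x)_i = c * D(x)_i * LET_d(x)_i = c * (N x)_i

**linear** in the fluence vector ``x``.  That linearity is what makes
per-voxel interval constraints in cDL space projectable, and it holds to
machine precision here because the identity is algebraic, not numeric.
The constant ``c`` defaults to 0.04 um/keV so cDL carries dose units
(Gy x keV/um x um/keV = Gy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

__all__ = [
    "DEFAULT_C",
    "InfluenceMatrix",
    "ForwardResult",
    "forward_dose",
    "forward_letd",
    "forward_cdl",
    "forward",
    "cdl_row",
]

#: default cDL scaling constant, um/keV
DEFAULT_C = 0.04


def _pattern(m: sparse.csr_matrix) -> sparse.csr_matrix:
    p = m.copy()
    p.data = np.ones_like(p.data)
    return p


class InfluenceMatrix:
    """Sparse per-beamlet influence components on a voxel grid.

    Parameters
    ----------
    dose : sparse matrix, shape (n_voxels, n_beamlets)
        Dose per primary, Gy.
    letd_numerator : sparse matrix, optional
        LET_d numerator per primary, Gy.keV/um.  Its sparsity pattern must
        be contained in the dose pattern and all entries must be >= 0.
    letd_denominator : sparse matrix, optional
        Exact LET_d denominator; kept for evaluation/reporting only (the
        forward model uses the denominator ~= dose simplification).
    grid : VoxelGrid, optional
        Geometry the voxel axis refers to.
    """

    def __init__(self, dose, letd_numerator=None, letd_denominator=None, grid=None, validate=True):
        self.components: dict[str, sparse.csr_matrix] = {}
        dose = sparse.csr_matrix(dose, dtype=float)
        dose.eliminate_zeros()
        self.components["dose"] = dose
        for name, mat in (("letd_numerator", letd_numerator), ("letd_denominator", letd_denominator)):
            if mat is not None:
                mat = sparse.csr_matrix(mat, dtype=float)
                mat.eliminate_zeros()
                self.components[name] = mat
        self.grid = grid
        if validate:
            self.validate()

    def validate(self) -> None:
        dose = self.components["dose"]
        if grid := self.grid:
            if grid.n_voxels != dose.shape[0]:
                raise ValueError(
                    f"grid has {grid.n_voxels} voxels but matrix has {dose.shape[0]} rows"
                )
        for name, mat in self.components.items():
            if mat.shape != dose.shape:
                raise ValueError(
                    f"component {name!r} shape {mat.shape} differs from dose shape {dose.shape}"
                )
            if mat.nnz and mat.data.min() < 0:
                raise ValueError(f"component {name!r} has negative entries")
        if "letd_numerator" in self.components:
            extra = _pattern(self.components["letd_numerator"]) - _pattern(dose)
            if extra.nnz and (extra.data > 0).any():
                raise ValueError(
                    "letd_numerator has entries outside the dose sparsity pattern"
                )

    @property
    def n_voxels(self) -> int:
        return self.components["dose"].shape[0]

    @property
    def n_beamlets(self) -> int:
        return self.components["dose"].shape[1]

    def component(self, name: str) -> sparse.csr_matrix:
        try:
            return self.components[name]
        except KeyError:
            raise KeyError(
                f"influence matrix has no {name!r} component; available: {list(self.components)}"
            ) from None

    @property
    def dose(self) -> sparse.csr_matrix:
        return self.components["dose"]

    @property
    def letd_numerator(self) -> sparse.csr_matrix:
        return self.component("letd_numerator")


@dataclass(frozen=True)
class ForwardResult:
    """Per-voxel dose, LET_d and cDL images for one fluence vector.

    ``cdl_i = c * dose_i * letd_i`` wherever ``dose_i`` exceeds the floor;
    LET_d is reported as 0 where the dose is at or below the floor (the
    declared convention for unirradiated voxels).
    """

    dose: np.ndarray
    letd: np.ndarray
    cdl: np.ndarray
    c: float = DEFAULT_C
    dose_floor: float = 0.0


def _check_fluence(infl: InfluenceMatrix, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size != infl.n_beamlets:
        raise ValueError(
            f"fluence vector length {x.size} does not match {infl.n_beamlets} beamlets"
        )
    if x.size and x.min() < 0:
        raise ValueError("fluence vector has negative entries")
    return x


def forward_dose(infl: InfluenceMatrix, x) -> np.ndarray:
    """Dose image ``D x`` (Gy); linear in ``x``."""
    x = _check_fluence(infl, x)
    return infl.dose @ x


def forward_letd(infl: InfluenceMatrix, x, dose_floor: float = 0.0) -> np.ndarray:
    """Dose-averaged LET image ``(N x) / (D x)`` (keV/um).

    Voxels with dose at or below ``dose_floor`` report 0 (no division
    warning); the floor suppresses noise-dominated LET in essentially
    unirradiated voxels.
    """
    x = _check_fluence(infl, x)
    num = infl.letd_numerator @ x
    den = infl.dose @ x
    out = np.zeros_like(den)
    good = den > max(dose_floor, 0.0)
    np.divide(num, den, out=out, where=good)
    return out


def forward_cdl(infl: InfluenceMatrix, x, c: float = DEFAULT_C, dose_floor: float = 0.0) -> np.ndarray:
    """cDL image ``c * dose * LET_d = c * (N x)`` (Gy).

    Computed through the linear identity, so it agrees with the
    dose-times-LET product to machine precision wherever the dose exceeds
    the floor.
    """
    if c <= 0:
        raise ValueError(f"constant c must be > 0, got {c}")
    x = _check_fluence(infl, x)
    cdl = c * (infl.letd_numerator @ x)
    if dose_floor > 0:
        cdl[infl.dose @ x <= dose_floor] = 0.0
    return cdl


def forward(infl: InfluenceMatrix, x, c: float = DEFAULT_C, dose_floor: float = 0.0) -> ForwardResult:
    """All three forward images at once."""
    return ForwardResult(
        dose=forward_dose(infl, x),
        letd=forward_letd(infl, x, dose_floor),
        cdl=forward_cdl(infl, x, c, dose_floor),
        c=c,
        dose_floor=dose_floor,
    )


def cdl_row(infl: InfluenceMatrix, voxel: int, c: float = DEFAULT_C) -> sparse.csr_matrix:
    """Sparse row ``a_i`` with ``<a_i, x> = cDL(x)_i`` for all ``x``.

    This is the constraint row the projection solver uses for cDL-space
    intervals: ``a_i = c * N_i``.
    """
    if not 0 <= voxel < infl.n_voxels:
        raise IndexError(f"voxel {voxel} outside grid with {infl.n_voxels} voxels")
    if c <= 0:
        raise ValueError(f"constant c must be > 0, got {c}")
    return c * infl.letd_numerator.getrow(voxel)
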