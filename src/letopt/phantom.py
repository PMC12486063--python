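"""Synthetic phantoms, spot lists and analytically structured influence matrices.

This module is the stand-in for a Monte Carlo particle-transport engine: it
produces voxel phantoms with parametric structures (spheres / boxes /
ellipsoids), multi-field spot lists, and sparse dose / LET_d influence
matrices with the physical structure the optimizer relies on:

* a single-peaked analytic depth--dose curve (plateau rising into a
  Gaussian Bragg peak at the range ``R0(E)``, with a sharp distal falloff),
* a monotone non-decreasing dose-averaged LET depth curve (entrance value
  rising to a distal value at the end of range -- the end-of-range LET
  elevation that motivates LET-aware planning),
* a lateral Gaussian beam profile whose sigma grows with depth,
* an LET_d numerator component defined **exactly** as
  ``N_ij = LET_d(depth) * D_ij``, so that the numerator/denominator
  additivity of dose-averaged LET holds to machine precision by
  construction.

The beam-model parameters are synthetic: they reproduce the qualitative
shape of proton pencil beams in water (Bragg--Kleeman range--energy law,
~mm peak widths, entrance LET ~2 keV/um rising toward ~10 keV/um at the
distal edge) but are not fitted to any clinical beam line.

Fields are axis-aligned: gantry angles are restricted to multiples of 90
degrees with the couch at 0, so beams travel along +/-x or +/-y and no
rotation/ray-tracing machinery is needed.  Gantry 0 maps to the +y axis,
90 to +x, 180 to -y, 270 to -x.  A spot's beam's-eye-view lateral
coordinates (x_mm, y_mm) map onto the two grid axes orthogonal to the beam
direction (first the remaining in-plane axis, then z), offset by the field
isocenter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import sparse

from .grid import StructureSet, VoxelGrid
from .influence import InfluenceMatrix

__all__ = [
    "BeamModelParams",
    "StructureSpec",
    "Field",
    "SpotList",
    "make_phantom",
    "default_layout",
    "depth_dose",
    "depth_letd",
    "simulate_influence",
    "opposed_fields_spots",
]


@dataclass(frozen=True)
class BeamModelParams:
    """Parameters of the analytic pencil-beam model.

    range_coeff_mm, range_exponent
        Bragg--Kleeman range--energy law ``R0(E) = a * E**p`` with ``R0`` in
        mm and ``E`` in MeV.  Defaults (0.022, 1.77) approximate protons in
        water; ``R0`` is strictly increasing in ``E``.
    peak_width_mm
        Gaussian sigma of the Bragg peak (mm).
    entrance_to_peak
        Ratio of the entrance dose (depth 0) to the peak dose; the
        depth--dose curve is parametrised so this holds exactly.
    distal_cutoff_sigmas
        Dose is identically zero beyond ``R0 + distal_cutoff_sigmas *
        peak_width_mm`` (the distal edge).
    sigma0_mm, sigma_slope
        Lateral Gaussian sigma model ``sigma(d) = sigma0 + slope * d`` (mm).
    let_entrance, let_distal
        Dose-averaged LET (keV/um) at depth 0 and at the distal edge; the
        depth curve is piecewise-linear monotone between them, with the
        rise concentrated near the peak.
    energy_min_MeV, energy_max_MeV
        Validity window of the model; energies outside raise ``ValueError``.
    density_scale
        Dimensionless medium-density factor.  Effective depth is
        ``geometric depth / density_scale``, so a factor below 1 pulls the
        Bragg peak proximally.  Used by the +/-3.5 % robustness scenarios.
    dose_per_primary
        Peak dose amplitude per primary (relative Gy units).
    """

    range_coeff_mm: float = 0.022
    range_exponent: float = 1.77
    peak_width_mm: float = 6.0
    entrance_to_peak: float = 0.35
    distal_cutoff_sigmas: float = 4.0
    sigma0_mm: float = 7.0
    sigma_slope: float = 0.02
    let_entrance: float = 2.0
    let_distal: float = 10.0
    energy_min_MeV: float = 30.0
    energy_max_MeV: float = 250.0
    density_scale: float = 1.0
    dose_per_primary: float = 1.0

    def __post_init__(self) -> None:
        if self.range_coeff_mm <= 0 or self.range_exponent <= 0:
            raise ValueError("range-energy law must be strictly increasing (a > 0, p > 0)")
        if self.peak_width_mm <= 0:
            raise ValueError("peak_width_mm must be > 0")
        if not 0 < self.entrance_to_peak <= 1:
            raise ValueError("entrance_to_peak must be in (0, 1]")
        if self.sigma0_mm <= 0 or self.sigma_slope < 0:
            raise ValueError("lateral sigma model must be positive at all depths")
        if self.let_distal < self.let_entrance:
            raise ValueError("LET_d depth curve must be non-decreasing (let_distal >= let_entrance)")
        if self.density_scale <= 0:
            raise ValueError("density_scale must be > 0")

    def range_mm(self, energy_MeV: float) -> float:
        """Bragg-peak depth ``R0(E)`` in mm."""
        self._check_energy(energy_MeV)
        return self.range_coeff_mm * float(energy_MeV) ** self.range_exponent

    def distal_edge_mm(self, energy_MeV: float) -> float:
        return self.range_mm(energy_MeV) + self.distal_cutoff_sigmas * self.peak_width_mm

    def energy_for_range(self, range_mm: float) -> float:
        """Inverse of the range--energy law (mm -> MeV)."""
        return (range_mm / self.range_coeff_mm) ** (1.0 / self.range_exponent)

    def _check_energy(self, energy_MeV: float) -> None:
        if not self.energy_min_MeV <= energy_MeV <= self.energy_max_MeV:
            raise ValueError(
                f"energy {energy_MeV} MeV outside model table "
                f"[{self.energy_min_MeV}, {self.energy_max_MeV}] MeV"
            )


def depth_dose(depth_mm, energy_MeV: float, params: BeamModelParams) -> np.ndarray:
    """Analytic depth--dose per primary at depth(s) ``depth_mm`` (mm).

    Single-peaked: the proximal part rises from ``entrance_to_peak * peak``
    at depth 0 to the peak at ``R0(E)``; the distal part is a Gaussian
    falloff, identically zero beyond the distal cutoff.  The entrance value
    is exact by parametrisation (the proximal Gaussian is renormalised so
    its contribution vanishes at depth 0).
    """
    d = np.asarray(depth_mm, dtype=float)
    if np.any(d < 0):
        raise ValueError("depth must be >= 0")
    r0 = params.range_mm(energy_MeV)
    w = params.peak_width_mm
    ratio = params.entrance_to_peak
    peak = params.dose_per_primary

    g = np.exp(-((d - r0) ** 2) / (2.0 * w * w))
    g0 = math.exp(-(r0 * r0) / (2.0 * w * w))
    proximal = peak * (ratio + (1.0 - ratio) * (g - g0) / (1.0 - g0))
    distal = peak * g
    out = np.where(d <= r0, proximal, distal)
    out = np.where(d >= r0 + params.distal_cutoff_sigmas * w, 0.0, out)
    return out if out.ndim else float(out)


def depth_letd(depth_mm, energy_MeV: float, params: BeamModelParams) -> np.ndarray:
    """Dose-averaged LET (keV/um) at depth(s) ``depth_mm``.

    Piecewise-linear and monotone non-decreasing from the entrance value at
    depth 0 to the distal value at the distal edge ``R0 + cutoff * width``;
    constant beyond (where the dose is zero anyway).  The rise is
    concentrated near the Bragg peak: 20 % of the increase is spread over
    the plateau, the remaining 80 % over the last ~3 peak widths.
    """
    d = np.asarray(depth_mm, dtype=float)
    if np.any(d < 0):
        raise ValueError("depth must be >= 0")
    r0 = params.range_mm(energy_MeV)
    w = params.peak_width_mm
    edge = r0 + params.distal_cutoff_sigmas * w
    l0, l1 = params.let_entrance, params.let_distal
    knee = max(0.0, r0 - 3.0 * w)
    xp = [0.0, knee, edge] if knee > 0 else [0.0, edge]
    fp = [l0, l0 + 0.2 * (l1 - l0), l1] if knee > 0 else [l0, l1]
    out = np.interp(d, xp, fp)
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# Phantom construction


@dataclass(frozen=True)
class StructureSpec:
    """Parametric structure: a sphere, box or ellipsoid in mm coordinates.

    ``center_mm`` is relative to the grid centre.  ``size_mm`` is the radius
    for a sphere, the half-extents (3-tuple) for a box or ellipsoid.
    ``priority`` resolves overlaps: the higher-priority structure claims
    shared voxels; overlap between a target and an OAR with no priority on
    either is an error.
    """

    name: str
    role: str
    shape: str = "sphere"
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    size_mm: float | tuple[float, float, float] = 9.0
    priority: int | None = None

    def half_extents(self) -> np.ndarray:
        if np.isscalar(self.size_mm):
            return np.full(3, float(self.size_mm))
        return np.asarray(self.size_mm, dtype=float)


def default_layout(ptv_radius_mm: float = 9.0, oar_gap_mm: float = 0.0) -> list[StructureSpec]:
    """Centred spherical PTV with a box OAR abutting its +x pole.

    With the default opposed fields along x, the OAR sits on the beam axis:
    distal to one field, in the entrance channel of the other -- a
    brainstem-like critical structure in the beam path, where end-of-range
    LET elevation is the clinical concern and the opposed field offers a
    low-LET escape route for the optimizer.
    """
    oar_half = (6.0, ptv_radius_mm, ptv_radius_mm)
    return [
        StructureSpec("PTV", "target", "sphere", (0.0, 0.0, 0.0), ptv_radius_mm),
        StructureSpec(
            "OAR",
            "oar",
            "box",
            (ptv_radius_mm + oar_gap_mm + oar_half[0], 0.0, 0.0),
            oar_half,
        ),
    ]


def _shape_mask(grid: VoxelGrid, spec: StructureSpec) -> np.ndarray:
    centers = grid.voxel_centers() - grid.center_mm()
    rel = centers - np.asarray(spec.center_mm)
    he = spec.half_extents()
    if spec.shape == "sphere":
        if not np.isscalar(spec.size_mm):
            raise ValueError(f"sphere {spec.name!r} needs a scalar radius")
        flat = (rel**2).sum(axis=1) <= float(spec.size_mm) ** 2
    elif spec.shape == "ellipsoid":
        flat = ((rel / he) ** 2).sum(axis=1) <= 1.0
    elif spec.shape == "box":
        flat = np.all(np.abs(rel) <= he, axis=1)
    else:
        raise ValueError(f"unknown shape {spec.shape!r} for structure {spec.name!r}")
    return grid.unflatten(flat)


def make_phantom(
    dims: tuple[int, int, int],
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0),
    layout: list[StructureSpec] | None = None,
    seed: int = 0,
    jitter_mm: float = 0.0,
) -> tuple[VoxelGrid, StructureSet]:
    """Build a voxel grid and structure masks from a parametric layout.

    Deterministic: identical ``(dims, spacing, layout, seed)`` give
    bit-identical masks.  ``jitter_mm`` optionally perturbs structure
    centres with a seeded RNG (off by default).

    Raises
    ------
    ValueError
        If a structure extends beyond the grid, or a target and an OAR
        overlap with no priority declared on either.
    """
    grid = VoxelGrid(dims, spacing, origin=tuple(s / 2.0 for s in spacing))
    layout = list(layout) if layout is not None else default_layout()
    if not any(s.role == "target" for s in layout):
        raise ValueError("layout must declare a target structure")

    rng = np.random.default_rng(seed)
    specs = []
    for spec in layout:
        if jitter_mm > 0:
            delta = rng.uniform(-jitter_mm, jitter_mm, size=3)
            spec = replace(spec, center_mm=tuple(np.asarray(spec.center_mm) + delta))
        specs.append(spec)

    half_grid = np.asarray(grid.extent_mm) / 2.0
    masks: dict[str, np.ndarray] = {}
    for spec in specs:
        lo = np.asarray(spec.center_mm) - spec.half_extents()
        hi = np.asarray(spec.center_mm) + spec.half_extents()
        if np.any(lo < -half_grid) or np.any(hi > half_grid):
            raise ValueError(
                f"structure {spec.name!r} exceeds the grid extent "
                f"({tuple(grid.extent_mm)} mm)"
            )
        masks[spec.name] = _shape_mask(grid, spec)

    # overlap resolution: priority claims the voxel; no priority -> error
    by_name = {s.name: s for s in specs}
    names = list(masks)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            na, nb = names[a], names[b]
            overlap = masks[na] & masks[nb]
            if not overlap.any():
                continue
            pa, pb = by_name[na].priority, by_name[nb].priority
            if pa is None and pb is None:
                raise ValueError(
                    f"structures {na!r} and {nb!r} overlap and neither declares a priority"
                )
            if (pa or 0) >= (pb or 0):
                masks[nb] &= ~overlap
            else:
                masks[na] &= ~overlap

    structures = StructureSet(grid)
    for spec in specs:
        structures.add(spec.name, masks[spec.name], spec.role)
    return grid, structures


# --------------------------------------------------------------------------
# Spot lists


@dataclass(frozen=True)
class Field:
    """One treatment field: axis-aligned beam geometry."""

    field_id: int
    gantry_deg: float = 0.0
    couch_deg: float = 0.0
    isocenter_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def direction(self) -> tuple[int, np.ndarray]:
        """Beam axis index (0=x, 1=y) and unit direction vector."""
        if self.couch_deg % 360 != 0:
            raise ValueError("couch rotation is not supported (couch_deg must be 0)")
        g = self.gantry_deg % 360
        mapping = {0: (1, +1), 90: (0, +1), 180: (1, -1), 270: (0, -1)}
        if g not in mapping:
            raise ValueError(
                f"gantry angle {self.gantry_deg} not supported; must be a multiple of 90 deg"
            )
        axis, sign = mapping[g]
        e = np.zeros(3)
        e[axis] = sign
        return axis, e


SPOT_COLUMNS = ["field_id", "x_mm", "y_mm", "energy_MeV", "fluence"]


@dataclass
class SpotList:
    """Per-field pencil-beam spots with initial fluences.

    ``spots`` is a DataFrame with columns ``field_id, x_mm, y_mm,
    energy_MeV, fluence``; lateral positions are in the beam's-eye view.
    """

    fields: dict[int, Field]
    spots: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.spots.columns]
        if missing:
            raise ValueError(f"spot table missing columns {missing}")
        self.spots = self.spots[SPOT_COLUMNS].reset_index(drop=True)
        if (self.spots["fluence"] < 0).any():
            raise ValueError("spot fluences must be >= 0")
        undeclared = set(self.spots["field_id"]) - set(self.fields)
        if undeclared:
            raise ValueError(f"spots reference undeclared field ids {sorted(undeclared)}")

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    def fluence_vector(self) -> np.ndarray:
        return self.spots["fluence"].to_numpy(dtype=float)

    def with_fluence(self, x: np.ndarray) -> "SpotList":
        df = self.spots.copy()
        df["fluence"] = np.asarray(x, dtype=float)
        return SpotList(self.fields, df)


def opposed_fields_spots(
    grid: VoxelGrid,
    target_mask: np.ndarray,
    params: BeamModelParams,
    n_energy_layers: int = 5,
    lateral_spacing_mm: float = 10.5,
    lateral_margin_mm: float = 9.0,
    depth_margin_mm: float = 5.0,
    fluence: float = 1.0,
) -> SpotList:
    """Two opposed fields along x (gantry 90/270) covering a target mask.

    Energy layers place Bragg peaks evenly across the target's depth extent
    extended by ``depth_margin_mm`` on both ends, and the lateral spot
    lattice covers the target's beam's-eye-view footprint plus
    ``lateral_margin_mm`` -- the margins keep every target voxel interior
    to the spot footprint, so a uniform fluence already gives a nearly
    homogeneous target dose (the margins play the role spot placement
    margins play in clinical planning).  A convenience generator for
    phantom studies; clinical spot sequencing is out of scope.
    """
    flat = grid.flatten(np.asarray(target_mask, dtype=bool))
    if not flat.any():
        raise ValueError("target mask is empty")
    centers = grid.voxel_centers()[flat]
    center = grid.center_mm()
    iso = tuple(center)

    rows = []
    fields = {}
    for fid, gantry in ((0, 90.0), (1, 270.0)):
        fld = Field(fid, gantry_deg=gantry, couch_deg=0.0, isocenter_mm=iso)
        fields[fid] = fld
        axis, e = fld.direction()
        # depth of target voxels along this beam, from the grid entry face
        entry = (
            grid.origin[axis] - grid.spacing[axis] / 2.0
            if e[axis] > 0
            else grid.origin[axis] + (grid.dims[axis] - 0.5) * grid.spacing[axis]
        )
        depths = (centers[:, axis] - entry) * e[axis]
        d_lo = max(depths.min() - depth_margin_mm, params.range_mm(params.energy_min_MeV))
        d_hi = depths.max() + depth_margin_mm
        ranges = np.linspace(d_lo, d_hi, n_energy_layers)
        # lateral footprint (u = remaining in-plane axis, v = z), iso-centred
        u_axis = 1 - axis
        u = centers[:, u_axis] - iso[u_axis]
        v = centers[:, 2] - iso[2]
        r_max = float(np.sqrt(u**2 + v**2).max()) + lateral_margin_mm
        n_side = max(1, int(math.floor(2 * r_max / lateral_spacing_mm)) + 1)
        lat = (np.arange(n_side) - (n_side - 1) / 2.0) * lateral_spacing_mm
        for r0 in ranges:
            energy = params.energy_for_range(r0)
            for su in lat:
                for sv in lat:
                    if su * su + sv * sv > r_max * r_max:
                        continue
                    rows.append((fid, su, sv, energy, fluence))
    spots = pd.DataFrame(rows, columns=SPOT_COLUMNS)
    return SpotList(fields, spots)


# --------------------------------------------------------------------------
# Influence simulation


def simulate_influence(
    grid: VoxelGrid,
    spots: SpotList,
    params: BeamModelParams,
    *,
    patient_shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    sparsity_rel_floor: float = 1e-4,
    with_denominator: bool = False,
) -> InfluenceMatrix:
    """Compute sparse dose and LET_d-numerator influence matrices.

    For beamlet ``j`` and voxel ``i``::

        D_ij = depth_dose(d_i) * exp(-r_i^2 / (2 sigma(d_i)^2))
        N_ij = depth_letd(d_i) * D_ij

    with ``d_i`` the effective depth of the voxel centre along the beam
    (geometric depth divided by ``params.density_scale``) and ``r_i`` its
    lateral distance from the spot axis.  The exact ``N = LET * D``
    relation makes dose-averaged LET numerator/denominator additivity hold
    to machine precision.

    ``patient_shift_mm`` rigidly shifts the patient (grid) relative to the
    beams, used by the setup-error robustness scenarios.  Entries below
    ``sparsity_rel_floor`` times the column maximum are dropped.

    Raises
    ------
    ValueError
        If no spot deposits any dose in the grid.
    """
    centers = grid.voxel_centers() - np.asarray(patient_shift_mm, dtype=float)
    n_vox = grid.n_voxels
    cols_d, cols_n, rows_idx, col_id = [], [], [], []

    df = spots.spots
    for j, spot in enumerate(df.itertuples(index=False)):
        fld = spots.fields[int(spot.field_id)]
        axis, e = fld.direction()
        entry = (
            grid.origin[axis] - grid.spacing[axis] / 2.0
            if e[axis] > 0
            else grid.origin[axis] + (grid.dims[axis] - 0.5) * grid.spacing[axis]
        )
        depth_geom = (centers[:, axis] - entry) * e[axis]
        inside = depth_geom >= 0
        d_eff = depth_geom[inside] / params.density_scale

        u_axis = 1 - axis
        iso = fld.isocenter_mm
        du = centers[inside, u_axis] - (iso[u_axis] + spot.x_mm)
        dv = centers[inside, 2] - (iso[2] + spot.y_mm)
        sigma = params.sigma0_mm + params.sigma_slope * d_eff
        dd = depth_dose(d_eff, spot.energy_MeV, params)
        dose = dd * np.exp(-(du * du + dv * dv) / (2.0 * sigma * sigma))

        if dose.size == 0 or dose.max() <= 0:
            continue
        keep = dose >= sparsity_rel_floor * dose.max()
        keep &= dose > 0
        if not keep.any():
            continue
        let = depth_letd(d_eff[keep], spot.energy_MeV, params)
        vox = np.flatnonzero(inside)[keep]
        rows_idx.append(vox)
        cols_d.append(dose[keep])
        cols_n.append(let * dose[keep])
        col_id.append(np.full(vox.size, j))

    if not rows_idx:
        raise ValueError("no spot deposits dose in the grid (all-zero influence matrix)")

    rows = np.concatenate(rows_idx)
    cols = np.concatenate(col_id)
    d_data = np.concatenate(cols_d)
    n_data = np.concatenate(cols_n)
    shape = (n_vox, spots.n_spots)
    dij = sparse.csr_matrix((d_data, (rows, cols)), shape=shape)
    nij = sparse.csr_matrix((n_data, (rows, cols)), shape=shape)
    den = dij.copy() if with_denominator else None
    return InfluenceMatrix(dose=dij, letd_numerator=nij, letd_denominator=den, grid=grid)
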