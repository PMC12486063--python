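"""Voxel grids and named structure masks.

Every image, mask, influence matrix and constraint in the package refers to a
:class:`VoxelGrid`.  Voxels are addressed either by an integer triple
``(i, j, k)`` or by a 0-based linear index with **x fastest**::

    idx = i + nx * (j + ny * k)

which is the Fortran-order ravel of an ``(nx, ny, nz)`` array.  Physical
voxel-centre positions follow the ITK convention::

    centre(i, j, k) = origin + (i, j, k) * spacing     [mm]

so ``origin`` is the centre of voxel ``(0, 0, 0)``, not the corner of the
volume.  The same ordering is declared in the sparse influence file header
and used by the MetaImage writer, so indices are bit-exact across the whole
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid", "StructureSet"]


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3D voxel lattice.

    Parameters
    ----------
    dims : tuple of int
        Number of voxels ``(nx, ny, nz)`` along each axis.
    spacing : tuple of float, optional
        Voxel size in mm per axis.  Default 3 mm isotropic, the resolution
        typically used for spot-scanning plan optimization.
    origin : tuple of float, optional
        Physical position (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(dims) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("dims, spacing and origin must be length-3")
        if any(d < 1 for d in dims):
            raise ValueError(f"dims must be >= 1 in each axis, got {dims}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be > 0, got {spacing}")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical edge length of the volume per axis (mm)."""
        return tuple(d * s for d, s in zip(self.dims, self.spacing))

    def linear_index(self, i, j, k):
        """Map voxel triple(s) to the 0-based x-fastest linear index."""
        nx, ny, _ = self.dims
        return np.asarray(i) + nx * (np.asarray(j) + ny * np.asarray(k))

    def unravel(self, idx):
        """Inverse of :meth:`linear_index`."""
        nx, ny, _ = self.dims
        idx = np.asarray(idx)
        i = idx % nx
        j = (idx // nx) % ny
        k = idx // (nx * ny)
        return i, j, k

    def voxel_centers(self) -> np.ndarray:
        """Physical centres of all voxels, shape ``(n_voxels, 3)`` mm.

        Row ``idx`` corresponds to linear index ``idx``.
        """
        nx, ny, nz = self.dims
        i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
        ijk = np.stack(
            [i.ravel(order="F"), j.ravel(order="F"), k.ravel(order="F")], axis=1
        )
        return np.asarray(self.origin) + ijk * np.asarray(self.spacing)

    def center_mm(self) -> np.ndarray:
        """Geometric centre of the volume (mm)."""
        return np.asarray(self.origin) + (np.asarray(self.dims) - 1) * np.asarray(self.spacing) / 2.0

    def flatten(self, volume: np.ndarray) -> np.ndarray:
        """Ravel an ``(nx, ny, nz)`` volume to linear-index order."""
        if volume.shape != self.dims:
            raise ValueError(f"volume shape {volume.shape} does not match grid dims {self.dims}")
        return volume.ravel(order="F")

    def unflatten(self, flat: np.ndarray) -> np.ndarray:
        """Reshape a linear-index vector back to ``(nx, ny, nz)``."""
        flat = np.asarray(flat)
        if flat.size != self.n_voxels:
            raise ValueError(f"vector length {flat.size} does not match grid with {self.n_voxels} voxels")
        return flat.reshape(self.dims, order="F")


_ROLES = ("target", "oar", "external")


@dataclass
class StructureSet:
    """Named boolean masks (PTV / OARs / external) over one grid.

    Masks may overlap; how overlaps are resolved into constraints is decided
    downstream (target priority by default, see the constraints module).
    """

    grid: VoxelGrid
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, mask: np.ndarray, role: str) -> None:
        if role not in _ROLES:
            raise ValueError(f"unknown role {role!r}; expected one of {_ROLES}")
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.grid.dims:
            raise ValueError(
                f"mask {name!r} has shape {mask.shape}, grid dims are {self.grid.dims}"
            )
        if role == "target" and not mask.any():
            raise ValueError(f"target structure {name!r} has an empty mask")
        self.masks[name] = mask
        self.roles[name] = role

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __iter__(self):
        return iter(self.masks)

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    def mask(self, name: str) -> np.ndarray:
        try:
            return self.masks[name]
        except KeyError:
            raise KeyError(f"no structure named {name!r}; have {self.names}") from None

    def flat(self, name: str) -> np.ndarray:
        """Boolean mask in linear-index order (length ``n_voxels``)."""
        return self.grid.flatten(self.mask(name))

    def by_role(self, role: str) -> list[str]:
        return [n for n, r in self.roles.items() if r == role]

    def targets(self) -> list[str]:
        return self.by_role("target")

    def oars(self) -> list[str]:
        return self.by_role("oar")

    def voxel_count(self, name: str) -> int:
        return int(self.mask(name).sum())
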