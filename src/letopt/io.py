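"""File formats: MetaImage volumes, sparse influence files, spot lists, masks.

3D scalar images travel as MetaImage (.mhd/.mha) through SimpleITK; the
voxel ordering on disk matches the package's x-fastest linear index, so a
flat vector round-trips bit-exactly.

The sparse influence container is a documented format of this package (not
a clone of any external binary layout): a text file with a magic line, a
one-line JSON header declaring shape, grid geometry, components, units and
the 0-based x-fastest voxel ordering, followed by per-beamlet blocks of
``voxel_index value...`` records.  Values are written as C99 hex floats
(``float.hex``) so write -> read reproduces every stored entry bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
from scipy import sparse

from .grid import StructureSet, VoxelGrid
from .influence import InfluenceMatrix
from .phantom import SPOT_COLUMNS, Field, SpotList

__all__ = [
    "read_metaimage",
    "write_metaimage",
    "read_sparse_influence",
    "write_sparse_influence",
    "read_spots",
    "write_spots",
    "read_structures",
    "write_structures",
]

SPARSE_MAGIC = "LETOPT-SPARSE"
SPARSE_VERSION = 1
_COMPONENT_UNITS = {
    "dose": "Gy/primary",
    "letd_numerator": "Gy*keV/um/primary",
    "letd_denominator": "Gy/primary",
}


# --------------------------------------------------------------------------
# MetaImage


def write_metaimage(values, grid: VoxelGrid, path) -> None:
    """Write a scalar volume (flat vector or (nx,ny,nz) array) as .mhd/.mha."""
    values = np.asarray(values, dtype=float)
    volume = grid.unflatten(values) if values.ndim == 1 else values
    if volume.shape != grid.dims:
        raise ValueError(f"volume shape {volume.shape} does not match grid dims {grid.dims}")
    # SimpleITK arrays are indexed [z, y, x]
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.T))
    img.SetSpacing(grid.spacing)
    img.SetOrigin(grid.origin)
    sitk.WriteImage(img, str(path))


def read_metaimage(path) -> tuple[VoxelGrid, np.ndarray]:
    """Read a 3D scalar .mhd/.mha; returns the grid and an (nx,ny,nz) array."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"{path}: expected a 3D image, got {img.GetDimension()}D")
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise ValueError(f"{path}: expected a scalar image, got vector-valued payload")
    volume = sitk.GetArrayFromImage(img).T  # back to [x, y, z]
    grid = VoxelGrid(dims=tuple(img.GetSize()), spacing=img.GetSpacing(), origin=img.GetOrigin())
    return grid, np.ascontiguousarray(volume)


# --------------------------------------------------------------------------
# Sparse influence format


def write_sparse_influence(infl: InfluenceMatrix, path) -> None:
    """Write all components of an influence matrix to the sparse text format."""
    components = list(infl.components)
    header = {
        "version": SPARSE_VERSION,
        "n_voxels": infl.n_voxels,
        "n_beamlets": infl.n_beamlets,
        "components": components,
        "units": {c: _COMPONENT_UNITS.get(c, "unknown") for c in components},
        "voxel_ordering": "0-based linear, x-fastest: idx = i + nx*(j + ny*k)",
    }
    if infl.grid is not None:
        header["grid"] = {
            "dims": list(infl.grid.dims),
            "spacing": list(infl.grid.spacing),
            "origin": list(infl.grid.origin),
        }
    csc = {name: mat.tocsc() for name, mat in infl.components.items()}
    dose = csc["dose"]
    with open(path, "w") as fh:
        fh.write(f"{SPARSE_MAGIC} {SPARSE_VERSION}\n")
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for j in range(infl.n_beamlets):
            lo, hi = dose.indptr[j], dose.indptr[j + 1]
            idx = dose.indices[lo:hi]
            fh.write(f"B {j} {idx.size}\n")
            # the union pattern equals the dose pattern (containment invariant)
            cols = []
            for name in components:
                col = np.zeros(infl.n_voxels)
                m = csc[name]
                clo, chi = m.indptr[j], m.indptr[j + 1]
                col[m.indices[clo:chi]] = m.data[clo:chi]
                cols.append(col)
            for i in idx:
                vals = " ".join(float(col[i]).hex() for col in cols)
                fh.write(f"{i} {vals}\n")


def read_sparse_influence(path) -> InfluenceMatrix:
    """Read the sparse influence format; bit-exact inverse of the writer."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such influence file: {path}")
    with open(path) as fh:
        magic = fh.readline().split()
        if len(magic) != 2 or magic[0] != SPARSE_MAGIC:
            raise ValueError(f"{path}: not a {SPARSE_MAGIC} file")
        if int(magic[1]) != SPARSE_VERSION:
            raise ValueError(
                f"{path}: format version {magic[1]} not supported (expected {SPARSE_VERSION})"
            )
        header = json.loads(fh.readline())
        n_vox, n_beam = header["n_voxels"], header["n_beamlets"]
        components = header["components"]
        rows, cols = [], []
        data = {name: [] for name in components}
        for j in range(n_beam):
            tag = fh.readline().split()
            if len(tag) != 3 or tag[0] != "B" or int(tag[1]) != j:
                raise ValueError(f"{path}: truncated or corrupt at beamlet {j}")
            count = int(tag[2])
            for _ in range(count):
                parts = fh.readline().split()
                if len(parts) != 1 + len(components):
                    raise ValueError(f"{path}: truncated record in beamlet {j}")
                rows.append(int(parts[0]))
                cols.append(j)
                for name, tok in zip(components, parts[1:]):
                    data[name].append(float.fromhex(tok))
    shape = (n_vox, n_beam)
    mats = {
        name: sparse.csr_matrix((data[name], (rows, cols)), shape=shape)
        for name in components
    }
    grid = None
    if "grid" in header:
        g = header["grid"]
        grid = VoxelGrid(tuple(g["dims"]), tuple(g["spacing"]), tuple(g["origin"]))
    return InfluenceMatrix(
        dose=mats["dose"],
        letd_numerator=mats.get("letd_numerator"),
        letd_denominator=mats.get("letd_denominator"),
        grid=grid,
    )


# --------------------------------------------------------------------------
# Spot lists (CSV with a JSON field-geometry comment) and structure masks


def write_spots(spots: SpotList, path) -> None:
    fields = {
        str(fid): {
            "gantry_deg": f.gantry_deg,
            "couch_deg": f.couch_deg,
            "isocenter_mm": list(f.isocenter_mm),
        }
        for fid, f in spots.fields.items()
    }
    with open(path, "w") as fh:
        fh.write("# fields " + json.dumps(fields, sort_keys=True) + "\n")
        spots.spots.to_csv(fh, index=False)


def read_spots(path) -> SpotList:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# fields "):
            raise ValueError(f"{path}: missing field-geometry header line")
        raw = json.loads(first[len("# fields "):])
        df = pd.read_csv(fh)
    fields = {
        int(fid): Field(
            int(fid),
            gantry_deg=spec["gantry_deg"],
            couch_deg=spec["couch_deg"],
            isocenter_mm=tuple(spec["isocenter_mm"]),
        )
        for fid, spec in raw.items()
    }
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: spot CSV missing columns {missing}")
    return SpotList(fields, df)


def write_structures(structures: StructureSet, out_dir) -> None:
    """One uint8 MetaImage per mask plus a roles.json sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in structures.names:
        write_metaimage(
            structures.mask(name).astype(float), structures.grid, out_dir / f"mask_{name}.mhd"
        )
    (out_dir / "roles.json").write_text(json.dumps(structures.roles, sort_keys=True))


def read_structures(in_dir) -> StructureSet:
    in_dir = Path(in_dir)
    roles_path = in_dir / "roles.json"
    if not roles_path.exists():
        raise FileNotFoundError(f"no roles.json in {in_dir}")
    roles = json.loads(roles_path.read_text())
    structures = None
    for name, role in roles.items():
        grid, volume = read_metaimage(in_dir / f"mask_{name}.mhd")
        if structures is None:
            structures = StructureSet(grid)
        structures.add(name, volume > 0.5, role)
    if structures is None:
        raise ValueError(f"{in_dir}: roles.json declares no structures")
    return structures
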