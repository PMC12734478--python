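"""Binary voxel representation of a membrane pore structure.

The central container is :class:`VoxelStructure`: a 3D boolean occupancy
grid (``True`` = pore, ``False`` = solid) with a physical voxel edge
length in nanometres.  The third array axis is the flow direction; index
0 is the reconstruction inlet (the open, large-pore side) and the last
index is the size-selective exit face.

Structures can be persisted either as NRRD (raw encoding, with voxel
size and axis metadata in the header) or as a flat ``.raw`` file with a
JSON sidecar.  Both round-trip bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = ["VoxelStructure", "save_structure", "load_structure"]

#: 6-connectivity structuring element (face-sharing neighbours only).
FACE_CONNECTIVITY = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class VoxelStructure:
    """Binary pore/solid grid with physical scale and flow-axis convention.

    Parameters
    ----------
    grid
        3D boolean array, ``True`` for pore voxels, ``False`` for solid.
        Axis 2 is the flow direction: slice ``grid[..., 0]`` is the
        inlet face and ``grid[..., -1]`` the size-selective exit face.
    voxel_size_nm
        Edge length of the (isotropic) cubic voxel in nanometres.
    provenance
        Free-text lineage tag (e.g. ``"generated(seed=7)"``).
    """

    grid: np.ndarray
    voxel_size_nm: float = 7.0
    provenance: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise ValueError(f"grid must be 3D, got shape {grid.shape}")
        if grid.dtype != bool:
            uniq = np.unique(grid)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("grid must be strictly binary (pore=1, solid=0)")
            grid = grid.astype(bool)
        if not self.voxel_size_nm > 0:
            raise ValueError("voxel_size_nm must be positive")
        object.__setattr__(self, "grid", grid)

    # -- basic geometry -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def n_slices(self) -> int:
        """Number of voxel layers along the flow axis."""
        return self.grid.shape[2]

    @property
    def thickness_um(self) -> float:
        """Physical depth of the structure along the flow axis, in µm."""
        return self.n_slices * self.voxel_size_nm * 1e-3

    def porosity(self) -> float:
        """Global pore-voxel fraction."""
        return float(self.grid.mean())

    def with_grid(self, grid: np.ndarray, provenance: str | None = None) -> "VoxelStructure":
        return replace(
            self,
            grid=grid,
            provenance=self.provenance if provenance is None else provenance,
        )

    # -- connectivity ----------------------------------------------------

    def percolates(self) -> bool:
        """True if a 6-connected pore path joins inlet and exit faces."""
        return percolating_pore_mask(self.grid) is not None

    def flow_connected_pores(self) -> np.ndarray:
        """Mask of pore voxels on some 6-connected inlet→exit path component.

        Returns the union of connected components that touch both the
        inlet and the exit face; empty mask if the structure does not
        percolate.
        """
        mask = percolating_pore_mask(self.grid)
        if mask is None:
            return np.zeros_like(self.grid)
        return mask


def percolating_pore_mask(grid: np.ndarray) -> np.ndarray | None:
    """Union of 6-connected pore components spanning inlet to exit, or None."""
    labels, n = ndimage.label(grid, structure=FACE_CONNECTIVITY)
    if n == 0:
        return None
    inlet = np.unique(labels[..., 0])
    exit_ = np.unique(labels[..., -1])
    spanning = np.intersect1d(inlet, exit_)
    spanning = spanning[spanning != 0]
    if spanning.size == 0:
        return None
    return np.isin(labels, spanning)


# -- persistence ---------------------------------------------------------
#
# NRRD support is intentionally minimal (raw encoding, the handful of
# header fields we need) since no NRRD library is part of the stack.

_NRRD_MAGIC = "NRRD0004"


def _write_nrrd(path: Path, s: VoxelStructure) -> None:
    data = s.grid.astype(np.uint8)
    sz = s.voxel_size_nm
    header = [
        _NRRD_MAGIC,
        "# poreflow voxel structure (pore=1, solid=0); axis 2 = flow, index 0 = inlet",
        "type: uint8",
        "dimension: 3",
        f"sizes: {data.shape[0]} {data.shape[1]} {data.shape[2]}",
        "space dimension: 3",
        "space units: \"nm\" \"nm\" \"nm\"",
        f"space directions: ({sz},0,0) (0,{sz},0) (0,0,{sz})",
        "kinds: space space space",
        "encoding: raw",
        "endian: little",
        f"content: {s.provenance}" if s.provenance else "content: poreflow",
        "",
    ]
    with open(path, "wb") as fh:
        fh.write("\n".join(header).encode("ascii"))
        fh.write(b"\n")
        # NRRD raw payload is in C (slowest-first) order of the declared sizes.
        fh.write(np.ascontiguousarray(data).tobytes())


def _read_nrrd(path: Path) -> VoxelStructure:
    with open(path, "rb") as fh:
        blob = fh.read()
    head, _, payload = blob.partition(b"\n\n")
    lines = head.decode("ascii").splitlines()
    if not lines or not lines[0].startswith("NRRD"):
        raise ValueError(f"{path} is not an NRRD file")
    fields: dict[str, str] = {}
    for line in lines[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        key, _, val = line.partition(":")
        fields[key.strip()] = val.strip()
    if fields.get("encoding") != "raw":
        raise ValueError("only raw-encoded NRRD is supported")
    if fields.get("type") not in ("uint8", "uchar", "unsigned char"):
        raise ValueError("only uint8 NRRD payloads are supported")
    sizes = tuple(int(t) for t in fields["sizes"].split())
    if "space directions" in fields:
        first = fields["space directions"].split(")")[0].lstrip("( ")
        voxel = float(first.split(",")[0])
    else:
        raise ValueError(f"{path}: missing voxel size metadata (space directions)")
    n = int(np.prod(sizes))
    data = np.frombuffer(payload[:n], dtype=np.uint8).reshape(sizes)
    return VoxelStructure(
        grid=data.astype(bool),
        voxel_size_nm=voxel,
        provenance=fields.get("content", ""),
    )


def _write_raw_json(path: Path, s: VoxelStructure) -> None:
    raw_path = path.with_suffix(".raw")
    meta = {
        "dims": list(s.shape),
        "voxel_size_nm": s.voxel_size_nm,
        "axis_order": "xyz, axis 2 = flow, index 0 = inlet",
        "dtype": "uint8",
        "provenance": s.provenance,
    }
    raw_path.write_bytes(np.ascontiguousarray(s.grid.astype(np.uint8)).tobytes())
    path.write_text(json.dumps(meta, indent=2))


def _read_raw_json(path: Path) -> VoxelStructure:
    meta = json.loads(path.read_text())
    if "voxel_size_nm" not in meta:
        raise ValueError(f"{path}: missing voxel_size_nm metadata; refusing to guess units")
    dims = tuple(meta["dims"])
    raw_path = path.with_suffix(".raw")
    data = np.frombuffer(raw_path.read_bytes(), dtype=np.uint8).reshape(dims)
    return VoxelStructure(
        grid=data.astype(bool),
        voxel_size_nm=float(meta["voxel_size_nm"]),
        provenance=meta.get("provenance", ""),
    )


def save_structure(path: str | Path, s: VoxelStructure) -> Path:
    """Persist a structure as ``.nrrd`` or ``.json`` (+ ``.raw``) by extension."""
    path = Path(path)
    if path.suffix == ".nrrd":
        _write_nrrd(path, s)
    elif path.suffix == ".json":
        _write_raw_json(path, s)
    else:
        raise ValueError(f"unsupported structure format: {path.suffix!r} (use .nrrd or .json)")
    return path


def load_structure(path: str | Path) -> VoxelStructure:
    """Load a structure written by :func:`save_structure`."""
    path = Path(path)
    if path.suffix == ".nrrd":
        return _read_nrrd(path)
    if path.suffix == ".json":
        return _read_raw_json(path)
    raise ValueError(f"unsupported structure format: {path.suffix!r}")
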