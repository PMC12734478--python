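"""Depth-resolved porosity and Euclidean-distance-map pore sizing.

Two morphometric summaries are computed from a binary structure:

* a porosity profile — pore-voxel fraction in consecutive slabs along
  the flow axis (default slab 250 nm), plotted at slab midpoints;
* a pore size distribution — for every pore voxel the exact Euclidean
  distance (voxel centre to voxel centre) to the nearest solid voxel,
  doubled and scaled by the voxel size to give a local pore diameter.

The distance map is computed on the full 3D structure and then sliced
to the requested depth slab, so pores are sized by their true 3D
surroundings rather than by the slab cross-section.  Domain faces are
open: no solid padding is added, which biases diameters of pores that
touch the lateral faces upward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .structure import VoxelStructure

__all__ = [
    "PorosityProfile",
    "PoreSizeDistribution",
    "porosity_profile",
    "pore_size_distribution",
]


@dataclass(frozen=True)
class PorosityProfile:
    """Porosity per depth slab along the flow axis."""

    midpoints_um: np.ndarray  # slab midpoints, µm from the inlet face
    porosity: np.ndarray  # pore-voxel fraction per slab, in [0, 1]
    slab_nm: float  # nominal slab thickness, nm
    slab_thickness_nm: np.ndarray  # true thickness per slab (last may be partial)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"depth_um": self.midpoints_um, "porosity": self.porosity})


@dataclass(frozen=True)
class PoreSizeDistribution:
    """Per-pore-voxel local diameters within one depth slab."""

    diameters_nm: np.ndarray  # one entry per pore voxel in the region
    bin_edges_nm: np.ndarray  # histogram bins, width = voxel size
    counts: np.ndarray
    region: tuple[int, int]  # [z0, z1) slice range along the flow axis
    voxel_size_nm: float

    def quantile(self, q) -> np.ndarray:
        return np.quantile(self.diameters_nm, q)

    def to_frame(self) -> pd.DataFrame:
        centers = 0.5 * (self.bin_edges_nm[:-1] + self.bin_edges_nm[1:])
        return pd.DataFrame({"diameter_nm": centers, "count": self.counts})


def porosity_profile(
    structure: VoxelStructure,
    slab_nm: float = 250.0,
    valid: np.ndarray | None = None,
) -> PorosityProfile:
    """Porosity in consecutive slabs of ``slab_nm`` along the flow axis.

    Parameters
    ----------
    structure
        Binary structure; axis 2 is depth (inlet at index 0).
    slab_nm
        Nominal slab thickness.  Rounded to a whole number of voxel
        layers; the final partial slab is reported with its true
        thickness.
    valid
        Optional boolean mask of voxels to count (e.g. excluding voxels
        shifted out of frame during alignment).  Default: all voxels.
    """
    h = structure.voxel_size_nm
    if slab_nm < h:
        raise ValueError(f"slab_nm={slab_nm} is below the voxel size {h} nm")
    grid = structure.grid
    nz = grid.shape[2]
    per_slab = max(1, round(slab_nm / h))

    mids, poro, thick = [], [], []
    for z0 in range(0, nz, per_slab):
        z1 = min(z0 + per_slab, nz)
        sub = grid[:, :, z0:z1]
        if valid is None:
            n_total = sub.size
            n_pore = int(sub.sum())
        else:
            v = valid[:, :, z0:z1]
            n_total = int(v.sum())
            n_pore = int((sub & v).sum())
        if n_total == 0:
            continue
        mids.append(0.5 * (z0 + z1) * h * 1e-3)
        poro.append(n_pore / n_total)
        thick.append((z1 - z0) * h)
    return PorosityProfile(
        midpoints_um=np.array(mids),
        porosity=np.array(poro),
        slab_nm=float(slab_nm),
        slab_thickness_nm=np.array(thick),
    )


def pore_size_distribution(
    structure: VoxelStructure,
    region: tuple[int, int] | None = None,
) -> PoreSizeDistribution:
    """Euclidean-distance-map pore diameters for one depth slab.

    For every pore voxel the exact Euclidean distance to the nearest
    solid voxel centre is computed on the full 3D grid; the local pore
    diameter is twice that distance times the voxel size.  The
    histogram uses bins one voxel wide.

    Parameters
    ----------
    region
        ``(z0, z1)`` half-open slice range along the flow axis; default
        the whole structure.
    """
    grid = structure.grid
    if not (~grid).any():
        raise ValueError("distance map undefined: structure contains no solid voxels")
    nz = grid.shape[2]
    if region is None:
        region = (0, nz)
    z0, z1 = region
    if not (0 <= z0 < z1 <= nz):
        raise ValueError(f"region {region} outside depth range [0, {nz}]")
    sub = grid[:, :, z0:z1]
    if not (~sub).any():
        raise ValueError("region contains no solid voxel; distances undefined")

    # Exact Euclidean distance from each pore voxel to the nearest solid
    # voxel centre, computed in full 3D then sliced.
    dist = ndimage.distance_transform_edt(grid)
    h = structure.voxel_size_nm
    diam = 2.0 * dist[:, :, z0:z1][sub] * h

    max_d = diam.max() if diam.size else h
    edges = np.arange(0.0, max_d + 2 * h, h)
    counts, edges = np.histogram(diam, bins=edges)
    return PoreSizeDistribution(
        diameters_nm=diam,
        bin_edges_nm=edges,
        counts=counts,
        region=(z0, z1),
        voxel_size_nm=h,
    )
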