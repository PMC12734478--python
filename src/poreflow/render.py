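"""Render FIB-SEM-like grayscale stacks from known voxel structures.

The renderer produces the acquisition artifacts that the stack
processing chain must undo, with the ground truth returned alongside:
per-slice integer lateral/vertical drift, additive Gaussian noise, a
slow multiplicative brightness drift along the milling direction, a
bright protein phase, and a flat bright carbon reference band at the
top of every slice (the protective deposition layer above the membrane
exit surface).  Because every corruption is known exactly, alignment,
enhancement, and segmentation can be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stacks import GrayscaleStack
from .structure import VoxelStructure
from .synthetic import substream

__all__ = ["RenderSpec", "render_stack"]


@dataclass(frozen=True)
class RenderSpec:
    """Acquisition model for synthetic serial-section imaging.

    drift
        (n_slices, 2) integer array of (dx, dy) pixel drifts per slice
        (dx = columns, dy = rows), or None for a drift-free stack.
    noise_sd
        Additive Gaussian noise, grayscale units.
    depth_gradient
        Per-slice multiplicative brightness factors along the milling
        direction (length n_slices), or None for unity.
    pore/solid/protein/carbon mean
        Phase intensities (8-bit-like scale); the background outside
        the membrane is rendered at the pore intensity.
    carbon_px
        Thickness of the carbon reference band in pixels (≥ 1).
    pad_px
        Margin of background pixels on every image edge; drifts beyond
        this margin would crop membrane content and raise an error.
    """

    drift: np.ndarray | None = None
    noise_sd: float = 6.0
    depth_gradient: np.ndarray | None = None
    pore_mean: float = 40.0
    solid_mean: float = 150.0
    protein_mean: float = 230.0
    carbon_mean: float = 210.0
    carbon_px: int = 10
    pad_px: int = 8

    def __post_init__(self) -> None:
        if self.carbon_px < 1:
            raise ValueError("carbon band must be at least 1 pixel thick")
        means = (self.pore_mean, self.solid_mean, self.protein_mean, self.carbon_mean)
        if len(set(means)) != len(means):
            raise ValueError("phase intensity means must be distinct")


def render_stack(
    structure: VoxelStructure,
    render: RenderSpec | None = None,
    protein_mask: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[GrayscaleStack, dict]:
    """Render one grayscale slice per structure layer along the milling axis.

    Slices are taken along structure axis 0; image rows run down the
    membrane depth with the exit face at the top, directly below the
    carbon band.  Returns the stack and a ground-truth record with the
    injected drifts, the true structure, the protein mask, and the
    nominal geometry metadata.
    """
    render = render or RenderSpec()
    nx, ny, nz = structure.shape
    n_slices = nx
    drift = render.drift
    if drift is None:
        drift = np.zeros((n_slices, 2), dtype=int)
    drift = np.asarray(drift, dtype=int)
    if drift.shape != (n_slices, 2):
        raise ValueError(f"drift must be ({n_slices}, 2), got {drift.shape}")
    if np.abs(drift).max() > render.pad_px:
        raise ValueError(
            f"drift up to {np.abs(drift).max()} px exceeds the {render.pad_px} px margin "
            "and would crop membrane content"
        )
    gradient = render.depth_gradient
    if gradient is None:
        gradient = np.ones(n_slices)
    gradient = np.asarray(gradient, dtype=float)
    if gradient.shape != (n_slices,):
        raise ValueError(f"depth_gradient must have length {n_slices}")

    pad = render.pad_px
    cpx = render.carbon_px
    H = pad + cpx + nz + pad
    W = pad + ny + pad
    carbon_rows = (pad, pad + cpx)
    membrane_rows = (pad + cpx, pad + cpx + nz)
    membrane_cols = (pad, pad + ny)

    if protein_mask is not None:
        protein_mask = np.asarray(protein_mask, dtype=bool)
        if protein_mask.shape != structure.shape:
            raise ValueError("protein mask must match the structure shape")

    rng = substream(seed, "render")
    data = np.empty((n_slices, H, W))
    for i in range(n_slices):
        img = np.full((H, W), render.pore_mean)
        img[carbon_rows[0] : carbon_rows[1], :] = render.carbon_mean
        # membrane cross-section: depth z maps to row r = top + (nz-1-z)
        section = np.where(structure.grid[i], render.pore_mean, render.solid_mean)
        if protein_mask is not None:
            section = np.where(protein_mask[i], render.protein_mean, section)
        img[membrane_rows[0] : membrane_rows[1], membrane_cols[0] : membrane_cols[1]] = (
            section.T[::-1, :]
        )
        dx, dy = drift[i]
        if dx or dy:
            shifted = np.full((H, W), render.pore_mean)
            ys = slice(max(dy, 0), min(H + dy, H))
            xs = slice(max(dx, 0), min(W + dx, W))
            shifted[ys, xs] = img[
                slice(max(-dy, 0), min(H - dy, H)), slice(max(-dx, 0), min(W - dx, W))
            ]
            img = shifted
        img = img * gradient[i]
        if render.noise_sd > 0:
            img = img + rng.normal(0.0, render.noise_sd, size=(H, W))
        data[i] = np.clip(img, 0.0, None)

    stack = GrayscaleStack(
        data=data,
        pixel_size_nm=structure.voxel_size_nm,
        slice_thickness_nm=structure.voxel_size_nm,
        carbon_rows=carbon_rows,
        membrane_rows=membrane_rows,
        membrane_cols=membrane_cols,
    )
    truth = {
        "drift": drift.copy(),
        "structure": structure,
        "protein_mask": None if protein_mask is None else protein_mask.copy(),
        "phase_means": {
            "pore": render.pore_mean,
            "solid": render.solid_mean,
            "protein": render.protein_mean,
            "carbon": render.carbon_mean,
        },
        "carbon_rows": carbon_rows,
        "membrane_rows": membrane_rows,
        "membrane_cols": membrane_cols,
    }
    return stack, truth
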