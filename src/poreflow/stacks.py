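"""Grayscale serial-section stacks: alignment, enhancement, segmentation.

A :class:`GrayscaleStack` holds the serial SEM images produced by
ion-beam milling: one 2D slice per milled section, stacked along the
milling direction.  Within each slice the membrane depth runs
vertically — the bright protective carbon band sits at the top of the
image, directly above the size-selective exit surface, and the
reconstruction inlet is toward the bottom.

Processing follows the reconstruction recipe for drifted FIB-SEM data:

1. :func:`align_stack` — per-slice vertical registration against the
   flat carbon band of the reference slice (normalized cross
   correlation), then residual horizontal registration by integer phase
   correlation between consecutive slices.  Shifts are integer-only; no
   interpolation ever touches pixel values, so pore shapes cannot be
   distorted, and pixels shifted out of frame are flagged invalid
   rather than cropped.
2. :func:`enhance_and_correct` — per-slice adaptive (tile-based,
   clip-limited) histogram equalization, then a depthwise intensity
   normalization dividing each slice by its low-pass background
   estimate so mean brightness is flat across the stack.
3. :func:`segment_two_zone` — the depth range is split into two zones
   thresholded independently (Otsu unless manual thresholds are given;
   dark = pore, bright = solid/protein) and concatenated into a single
   binary :class:`~poreflow.structure.VoxelStructure`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage import exposure, filters
from skimage.registration import phase_cross_correlation

from .structure import VoxelStructure

__all__ = [
    "GrayscaleStack",
    "DriftTrace",
    "SegmentationResult",
    "align_stack",
    "enhance_and_correct",
    "segment_two_zone",
    "save_stack",
    "load_stack",
]


@dataclass(frozen=True)
class GrayscaleStack:
    """Serial 2D grayscale slices with geometry metadata.

    ``data`` has shape (n_slices, H, W): slice index runs along the
    milling direction, image rows along membrane depth (exit at the
    top), columns along the remaining lateral axis.  ``carbon_rows``
    and ``membrane_rows``/``membrane_cols`` give the nominal (drift-free)
    row/column ranges of the carbon reference band and of the membrane
    content.  ``valid`` flags pixels that remained in frame through all
    shifts (None means all valid).
    """

    data: np.ndarray
    pixel_size_nm: float = 7.0
    slice_thickness_nm: float = 7.0
    carbon_rows: tuple[int, int] = (0, 0)
    membrane_rows: tuple[int, int] = (0, 0)
    membrane_cols: tuple[int, int] = (0, 0)
    valid: np.ndarray | None = None
    drift: "DriftTrace | None" = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError("stack data must be (n_slices, H, W)")
        if self.slice_thickness_nm <= 0:
            raise ValueError("slice thickness must be positive")
        object.__setattr__(self, "data", data)

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def valid_mask(self) -> np.ndarray:
        if self.valid is None:
            return np.ones_like(self.data, dtype=bool)
        return self.valid


@dataclass(frozen=True)
class DriftTrace:
    """Estimated per-slice drift (pixels) relative to the reference slice."""

    dx: np.ndarray  # column drift per slice
    dy: np.ndarray  # row drift per slice
    method: str = "template+phase"

    def __post_init__(self) -> None:
        dx = np.asarray(self.dx, dtype=int)
        dy = np.asarray(self.dy, dtype=int)
        if dx.shape != dy.shape:
            raise ValueError("dx and dy must have the same length")
        object.__setattr__(self, "dx", dx)
        object.__setattr__(self, "dy", dy)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slice": np.arange(len(self.dx)),
                "dx": self.dx,
                "dy": self.dy,
                "method": self.method,
            }
        )


def _shift_image(img: np.ndarray, dy: int, dx: int, fill: float) -> tuple[np.ndarray, np.ndarray]:
    """Integer shift with fill; returns (shifted, in-frame mask)."""
    out = np.full_like(img, fill)
    ok = np.zeros(img.shape, dtype=bool)
    H, W = img.shape
    ys = slice(max(dy, 0), min(H + dy, H))
    xs = slice(max(dx, 0), min(W + dx, W))
    ys_src = slice(max(-dy, 0), min(H - dy, H))
    xs_src = slice(max(-dx, 0), min(W - dx, W))
    out[ys, xs] = img[ys_src, xs_src]
    ok[ys, xs] = True
    return out, ok


def align_stack(
    stack: GrayscaleStack,
    template_rows: tuple[int, int] | None = None,
    max_shift: int | None = None,
    corr_floor: float = 0.5,
) -> tuple[GrayscaleStack, DriftTrace]:
    """Two-step drift correction using the carbon band as the template.

    Step 1: for every slice, the vertical offset maximizing the
    normalized cross correlation between the reference slice's carbon
    band rows and the same rows of that slice.  Step 2: the residual
    horizontal offset by integer phase correlation between consecutive
    vertically aligned slices, accumulated relative to slice 0.  Slices
    are then shifted by the negated integer drift; pixel values are
    never interpolated, and out-of-frame pixels are marked invalid.
    """
    data = stack.data
    n, H, W = data.shape
    if template_rows is not None:
        r0, r1 = template_rows
    else:
        # include a few rows beyond the band: the flat carbon interior is
        # featureless, the vertical signal lives at its edges
        r0, r1 = stack.carbon_rows
        r0 = max(r0 - 4, 0)
        r1 = min(r1 + 4, H)
    if not (0 <= r0 < r1 <= H):
        raise ValueError(f"template rows ({r0}, {r1}) outside slice height {H}")
    template = data[0, r0:r1, :]
    if template.std() < 1e-12:
        raise RuntimeError("carbon template region has zero variance on slice 0")
    if max_shift is None:
        max_shift = min(r0, H - r1)

    # step 1: vertical NCC against the reference band
    dys = np.zeros(n, dtype=int)
    tmpl = (template - template.mean()) / template.std()
    for i in range(n):
        best, best_dy = -np.inf, 0
        for dy in range(-max_shift, max_shift + 1):
            win = data[i, r0 + dy : r1 + dy, :]
            s = win.std()
            if s < 1e-12:
                continue
            c = float((tmpl * (win - win.mean()) / s).mean())
            if c > best:
                best, best_dy = c, dy
        if best < corr_floor:
            raise RuntimeError(
                f"carbon-band correlation {best:.2f} below floor {corr_floor} on slice {i}"
            )
        dys[i] = best_dy

    # step 2: residual horizontal phase correlation, consecutive slices,
    # on the membrane rows (the carbon band is laterally featureless)
    m0, m1 = stack.membrane_rows if stack.membrane_rows != (0, 0) else (0, H)
    dxs = np.zeros(n, dtype=int)
    prev = _shift_image(data[0], -dys[0], 0, float(data[0].mean()))[0]
    for i in range(1, n):
        cur = _shift_image(data[i], -dys[i], 0, float(data[i].mean()))[0]
        shift, _, _ = phase_cross_correlation(
            prev[m0:m1, :], cur[m0:m1, :], upsample_factor=1, normalization=None
        )
        dxs[i] = dxs[i - 1] + int(round(-shift[1]))
        prev = cur

    dxs -= dxs[0]
    dys -= dys[0]

    aligned = np.empty_like(data)
    valid = np.zeros(data.shape, dtype=bool)
    prev_valid = stack.valid_mask()
    for i in range(n):
        fill = float(data[i].mean())
        aligned[i], ok = _shift_image(data[i], -dys[i], -dxs[i], fill)
        ok_prev = _shift_image(prev_valid[i].astype(float), -dys[i], -dxs[i], 0.0)[0] > 0.5
        valid[i] = ok & ok_prev

    trace = DriftTrace(dx=dxs, dy=dys)
    out = replace(stack, data=aligned, valid=valid, drift=trace)
    return out, trace


def enhance_and_correct(
    stack: GrayscaleStack,
    clahe_kernel: int | None = None,
    clahe_clip: float = 0.01,
    background_sigma: float | None = None,
) -> GrayscaleStack:
    """Adaptive histogram equalization plus depthwise intensity flattening.

    Each slice is passed through tile-based clip-limited equalization
    (8x8 tiles by default) and then divided by a large-kernel Gaussian
    background estimate, which removes the slow depthwise brightness
    drift; the output is rescaled to the input dynamic range.  Constant
    slices pass through unchanged with a warning.
    """
    data = stack.data
    n, H, W = data.shape
    vmax = float(data.max())
    if vmax <= 0:
        warnings.warn("stack has no positive intensities; passing through")
        return stack
    kernel = clahe_kernel or max(8, H // 8)
    sigma = background_sigma or max(H, W) / 4.0

    out = np.empty_like(data)
    for i in range(n):
        img = data[i]
        if img.std() < 1e-12:
            warnings.warn(f"slice {i} is constant; passed through unchanged")
            out[i] = img
            continue
        eq = exposure.equalize_adapthist(
            np.clip(img / vmax, 0.0, 1.0), kernel_size=kernel, clip_limit=clahe_clip
        )
        background = ndimage.gaussian_filter(eq, sigma)
        background = np.clip(background, background.max() * 1e-3, None)
        flat = eq / background
        out[i] = flat
    # common rescale so relative slice-to-slice brightness is preserved
    # only through the flattened values, back onto the input range
    omax = out.max()
    if omax > 0:
        out = out * (vmax / omax)
    return replace(stack, data=out)


@dataclass(frozen=True)
class SegmentationResult:
    """Binary structure from two-zone thresholding plus bookkeeping."""

    structure: VoxelStructure
    valid: np.ndarray  # per-voxel validity mask in structure axes
    thresholds: tuple[float, float]  # (lower zone, upper zone) intensity cuts
    zone_boundary: int  # depth index of the zone split


def segment_two_zone(
    stack: GrayscaleStack,
    zone_boundary: int | None = None,
    manual_thresholds: tuple[float | None, float | None] | None = None,
) -> SegmentationResult:
    """Threshold the membrane region in two depth zones and assemble voxels.

    The membrane rows/cols of the stack are mapped to structure axes
    (slice index, column, depth), the depth range is split at
    ``zone_boundary`` (default mid-depth), and each zone is thresholded
    independently — automatically by Otsu's two-class criterion, or with
    the given manual intensity cuts.  Pixels darker than the cut are
    pore.  The carbon band never enters the structure; invalid
    (shifted-out) pixels are excluded from the histograms and flagged in
    the result.
    """
    r0, r1 = stack.membrane_rows
    c0, c1 = stack.membrane_cols
    if r1 <= r0 or c1 <= c0:
        raise ValueError("stack lacks membrane row/column metadata")
    nz = r1 - r0
    ny = c1 - c0
    n = stack.n_slices
    zb = zone_boundary if zone_boundary is not None else nz // 2
    if not 0 < zb < nz:
        raise ValueError(f"zone boundary {zb} must lie strictly inside (0, {nz})")

    img = stack.data[:, r0:r1, c0:c1]
    vmask = stack.valid_mask()[:, r0:r1, c0:c1]
    # structure axes: x = slice, y = column, z = depth (row r maps to
    # z = nz-1-(r-r0): image top is the exit face)
    vol = img[:, ::-1, :].transpose(0, 2, 1)
    vol_valid = vmask[:, ::-1, :].transpose(0, 2, 1)

    grid = np.zeros((n, ny, nz), dtype=bool)
    cuts = []
    zones = [(0, zb), (zb, nz)]
    for zi, (za, zj) in enumerate(zones):
        sub = vol[:, :, za:zj]
        sub_valid = vol_valid[:, :, za:zj]
        manual = manual_thresholds[zi] if manual_thresholds is not None else None
        if manual is None:
            vals = sub[sub_valid]
            if vals.std() < 1e-12:
                raise RuntimeError(
                    f"zone {zi} histogram is degenerate; supply a manual threshold"
                )
            t = float(filters.threshold_otsu(vals))
            lo_vals = vals[vals < t]
            hi_vals = vals[vals >= t]
            frac = lo_vals.size / vals.size
            # bimodality guard: Otsu on a single Gaussian yields class
            # separation ~2.7x the within-class spread; genuine two-phase
            # histograms sit far above that
            spread = 0.5 * (lo_vals.std() + hi_vals.std())
            sep = (hi_vals.mean() - lo_vals.mean()) / max(spread, 1e-12)
            if not 0.02 < frac < 0.98 or sep < 3.5:
                raise RuntimeError(
                    f"zone {zi} appears unimodal (class separation {sep:.1f}x spread, "
                    f"pore fraction {frac:.3f}); supply a manual threshold"
                )
        else:
            t = float(manual)
        cuts.append(t)
        grid[:, :, za:zj] = sub < t

    structure = VoxelStructure(
        grid=grid,
        voxel_size_nm=stack.pixel_size_nm,
        provenance="segmented(two-zone)",
    )
    return SegmentationResult(
        structure=structure,
        valid=vol_valid,
        thresholds=(cuts[0], cuts[1]),
        zone_boundary=zb,
    )


# ---------------------------------------------------------------------------
# persistence: multi-page TIFF + JSON sidecar
# ---------------------------------------------------------------------------


def save_stack(path: str | Path, stack: GrayscaleStack) -> Path:
    """Write a stack as multi-page TIFF with a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.data.astype(np.float32))
    meta = {
        "pixel_size_nm": stack.pixel_size_nm,
        "slice_thickness_nm": stack.slice_thickness_nm,
        "carbon_rows": list(stack.carbon_rows),
        "membrane_rows": list(stack.membrane_rows),
        "membrane_cols": list(stack.membrane_cols),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def load_stack(path: str | Path) -> GrayscaleStack:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    meta = json.loads(path.with_suffix(".json").read_text())
    return GrayscaleStack(
        data=data,
        pixel_size_nm=float(meta["pixel_size_nm"]),
        slice_thickness_nm=float(meta["slice_thickness_nm"]),
        carbon_rows=tuple(meta["carbon_rows"]),
        membrane_rows=tuple(meta["membrane_rows"]),
        membrane_cols=tuple(meta["membrane_cols"]),
    )
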