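"""Height-image conditioning, segmentation, and frame stitching.

Flattening removes per-scan-line polynomial background (fit to non-molecule
pixels only), segmentation applies an adaptive height threshold (per-tile
robust background + k*MAD), and stitching composites overlapping frames using
their known origins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_closing, binary_dilation, gaussian_filter, zoom
from skimage.measure import label as cc_label
from skimage.measure import regionprops

_MAD_SCALE = 1.4826  # normal-consistency factor for the median absolute deviation


@dataclass
class HeightImage:
    """A calibrated AFM height map.

    heights are in nm, indexed ``[row, col]``; ``origin_nm`` is the physical
    ``(x, y)`` position of pixel ``(0, 0)`` used when stitching frames.
    """

    heights: np.ndarray
    pixel_size_nm: float
    origin_nm: tuple[float, float] = (0.0, 0.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2D array")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if not self.pixel_size_nm > 0:
            raise ValueError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")
        self.origin_nm = (float(self.origin_nm[0]), float(self.origin_nm[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    def copy_with(self, heights: np.ndarray) -> "HeightImage":
        return HeightImage(heights, self.pixel_size_nm, self.origin_nm, dict(self.metadata))


@dataclass
class ComponentMask:
    """Integer-labeled connected components (0 = background)."""

    labels: np.ndarray
    pixel_size_nm: float
    areas_px: dict[int, int]
    bboxes: dict[int, tuple[int, int, int, int]]  # (min_row, min_col, max_row, max_col)

    @property
    def n_components(self) -> int:
        return len(self.areas_px)

    def component_ids(self) -> list[int]:
        return sorted(self.areas_px)

    def mask_of(self, comp_id: int) -> np.ndarray:
        return self.labels == comp_id


@dataclass(frozen=True)
class SegmentConfig:
    """Adaptive-threshold segmentation parameters.

    Foreground is grown by hysteresis: seed pixels exceed the background
    surface by ``k_mad`` robust sigmas (floored at ``min_height_nm``), and
    connected pixels above the ``k_low`` level (floored at
    ``min_height_low_nm``) are attached. Hysteresis keeps thin, faint
    backbone ridges connected without admitting isolated noise."""

    k_mad: float = 5.0
    k_low: float = 2.0
    tile_px: int = 128
    smooth_sigma_px: float = 1.0  # scale for seed detection
    min_height_nm: float = 0.10  # floor on seed threshold-above-background
    min_height_low_nm: float = 0.04  # floor on growth threshold
    ridge_sigma_along_px: float = 2.5  # oriented-filter extent along the ridge
    ridge_sigma_across_px: float = 0.9
    ridge_orientations: int = 8
    close_px: int = 2  # binary closing radius healing short ridge gaps
    dilate_px: int = 0  # optional extra ridge widening
    bridge_gap_px: float = 12.0  # link collinear fragment ends up to this gap
    bridge_iters: int = 4


def _foreground_guess(heights: np.ndarray, k: float = 2.0, grow_px: int = 2) -> np.ndarray:
    """First-pass foreground mask robust to per-line offsets.

    The mask is grown so the faint skirts of tip-broadened molecules do not
    leak into the background fits."""
    line_med = np.median(heights, axis=1, keepdims=True)
    resid = heights - line_med
    sigma = _MAD_SCALE * np.median(np.abs(resid - np.median(resid)))
    sigma = max(sigma, 1e-12)
    fg = resid > k * sigma
    # a scan line fully covered by a molecule hides from the per-line
    # criterion (its median IS the molecule); flag lines whose median is an
    # outlier among line medians
    lm = line_med.ravel()
    sig_lm = _MAD_SCALE * np.median(np.abs(lm - np.median(lm)))
    covered = (lm - np.median(lm)) > max(5.0 * sig_lm, 0.25)
    fg[covered, :] = True
    if grow_px > 0:
        fg = binary_dilation(fg, structure=np.ones((2 * grow_px + 1,) * 2, dtype=bool))
    return fg


def flatten(img: HeightImage, line_order: int = 1, max_iter: int = 10) -> HeightImage:
    """Remove per-scan-line polynomial background from a height image.

    A polynomial of ``line_order`` is least-squares fit to the non-molecule
    pixels of each scan line and subtracted. The molecule mask and fits are
    iterated to a fixed point, which makes the operation idempotent. Lines
    whose background pixel count cannot support the fit fall back to the
    global background fit (with a warning).
    """
    if line_order not in (0, 1, 2):
        raise ValueError(f"line_order must be 0, 1 or 2, got {line_order}")
    heights = img.heights.copy()
    n_rows, n_cols = heights.shape
    x = np.arange(n_cols, dtype=float)
    x = (x - x.mean()) / max(1.0, x.std())  # conditioned polynomial basis
    basis = np.vander(x, line_order + 1)
    min_bg = line_order + 2

    prev_mask = None
    for _ in range(max_iter):
        fg = _foreground_guess(heights)
        if prev_mask is not None and np.array_equal(fg, prev_mask):
            break
        prev_mask = fg
        bg = ~fg
        fallback_rows = []
        corrected = heights.copy()
        # global fit over all background pixels, for fully covered lines
        global_coef = None
        for r in range(n_rows):
            keep = bg[r]
            if keep.sum() < min_bg:
                fallback_rows.append(r)
                continue
            coef, *_ = np.linalg.lstsq(basis[keep], heights[r, keep], rcond=None)
            corrected[r] = heights[r] - basis @ coef
        if fallback_rows:
            keep = bg.ravel()
            if keep.sum() >= min_bg:
                big_basis = np.tile(basis, (n_rows, 1))
                global_coef, *_ = np.linalg.lstsq(
                    big_basis[keep], heights.ravel()[keep], rcond=None
                )
            warnings.warn(
                f"{len(fallback_rows)} scan line(s) fully covered by foreground; "
                "using global background fit",
                RuntimeWarning,
                stacklevel=2,
            )
            for r in fallback_rows:
                if global_coef is not None:
                    corrected[r] = heights[r] - basis @ global_coef
        heights = corrected
    return img.copy_with(heights)


def _background_surface(smoothed: np.ndarray, cfg: SegmentConfig) -> tuple[np.ndarray, float]:
    """Per-tile background median surface (upsampled) and global robust sigma."""
    n_rows, n_cols = smoothed.shape
    t = max(8, int(cfg.tile_px))
    tr = max(1, int(math.ceil(n_rows / t)))
    tc = max(1, int(math.ceil(n_cols / t)))
    med = np.empty((tr, tc))
    for i in range(tr):
        for j in range(tc):
            tile = smoothed[i * t : (i + 1) * t, j * t : (j + 1) * t]
            med[i, j] = np.median(tile)
    sigma = float(_MAD_SCALE * np.median(np.abs(smoothed - np.median(smoothed))))
    if med.shape == (1, 1):
        surface = np.full_like(smoothed, med[0, 0])
    else:
        surface = zoom(med, (n_rows / med.shape[0], n_cols / med.shape[1]), order=1, mode="nearest")
        surface = surface[:n_rows, :n_cols]
        if surface.shape != smoothed.shape:  # zoom rounding
            pad_r = n_rows - surface.shape[0]
            pad_c = n_cols - surface.shape[1]
            surface = np.pad(surface, ((0, pad_r), (0, pad_c)), mode="edge")
    return surface, sigma


def segment(
    img: HeightImage,
    min_area_px: int | None = None,
    threshold_cfg: SegmentConfig | None = None,
) -> ComponentMask:
    """Segment molecule-candidate components by adaptive height threshold.

    The threshold surface is per-tile background median plus
    ``k_mad`` * (global robust sigma); the comparison uses a Gaussian-smoothed
    copy of the image (sigma ``smooth_sigma_px``). Components smaller than
    ``min_area_px`` are dropped; remaining components are relabeled 1..K.
    """
    cfg = threshold_cfg or SegmentConfig()
    if min_area_px is None:
        min_area_px = default_min_area_px(img.pixel_size_nm)
    smoothed = gaussian_filter(img.heights, cfg.smooth_sigma_px) if cfg.smooth_sigma_px > 0 else img.heights
    surface, sigma = _background_surface(smoothed, cfg)
    excess = smoothed - surface
    high = max(cfg.k_mad * sigma, cfg.min_height_nm)
    seeds = excess > high
    # ridge continuity is judged with an oriented (anisotropic) filter bank
    response = _oriented_ridge_response(img.heights - surface, cfg)
    med_r = float(np.median(response))
    sigma_r = _MAD_SCALE * float(np.median(np.abs(response - med_r)))
    low = med_r + max(cfg.k_low * sigma_r, cfg.min_height_low_nm)
    low_mask = response > low
    fg = _reconstruct(seeds & low_mask, low_mask)
    if cfg.close_px > 0:
        fg = binary_closing(fg, structure=np.ones((2 * cfg.close_px + 1,) * 2, dtype=bool))
    if cfg.dilate_px > 0:
        fg = binary_dilation(fg, structure=np.ones((2 * cfg.dilate_px + 1,) * 2, dtype=bool))
    fg = _bridge_fragments(fg, cfg)
    raw = cc_label(fg, connectivity=2)
    labels = np.zeros_like(raw)
    areas: dict[int, int] = {}
    bboxes: dict[int, tuple[int, int, int, int]] = {}
    next_id = 1
    for prop in regionprops(raw):
        if prop.area < min_area_px:
            continue
        labels[raw == prop.label] = next_id
        areas[next_id] = int(prop.area)
        bboxes[next_id] = tuple(int(v) for v in prop.bbox)
        next_id += 1
    return ComponentMask(labels, img.pixel_size_nm, areas, bboxes)


def _oriented_ridge_response(excess: np.ndarray, cfg: SegmentConfig) -> np.ndarray:
    """Maximum response over a bank of anisotropic Gaussian kernels.

    Averaging along the (locally straight) backbone while staying narrow
    across it suppresses isotropic pixel noise far better than any isotropic
    filter can for a ~1-px-wide ridge."""
    from scipy.signal import fftconvolve

    sa, sc = cfg.ridge_sigma_along_px, cfg.ridge_sigma_across_px
    half = int(math.ceil(3.0 * sa))
    ax = np.arange(-half, half + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    best = None
    for i in range(cfg.ridge_orientations):
        theta = math.pi * i / cfg.ridge_orientations
        u = xx * math.cos(theta) + yy * math.sin(theta)
        v = -xx * math.sin(theta) + yy * math.cos(theta)
        kern = np.exp(-0.5 * (u / sa) ** 2 - 0.5 * (v / sc) ** 2)
        kern /= kern.sum()
        resp = fftconvolve(excess, kern, mode="same")
        best = resp if best is None else np.maximum(best, resp)
    return best


def _skeleton_endpoints(skel: np.ndarray) -> np.ndarray:
    """(n, 2) row/col coordinates of skeleton pixels with exactly 1 neighbor."""
    from scipy.ndimage import convolve

    k = np.ones((3, 3), dtype=int)
    k[1, 1] = 0
    nb = convolve(skel.astype(int), k, mode="constant")
    pts = np.argwhere(skel & (nb == 1))
    return pts


def _bridge_fragments(fg: np.ndarray, cfg: SegmentConfig) -> np.ndarray:
    """Link broken backbone fragments end-to-end.

    A faint ridge can dip below the detection threshold for a few pixels;
    such breaks leave two fragment ends that are close together and roughly
    collinear. Draw a short bridge between qualifying end pairs. Side-by-side
    molecules are not affected because only *end* pixels participate and the
    end directions must point at each other.
    """
    from scipy.spatial import cKDTree
    from skimage.draw import line as draw_line
    from skimage.morphology import skeletonize as _skel

    max_gap = cfg.bridge_gap_px
    if max_gap <= 0:
        return fg
    out = fg.copy()
    for _ in range(max(1, cfg.bridge_iters)):
        lab = cc_label(out, connectivity=2)
        if lab.max() <= 1:
            break
        skel = _skel(out)
        ends = _skeleton_endpoints(skel)
        if len(ends) < 2:
            break
        comp_of = lab[ends[:, 0], ends[:, 1]]
        # outward direction at each end: from local skeleton centroid to end
        dirs = np.zeros((len(ends), 2))
        sk_pts = np.argwhere(skel)
        sk_tree = cKDTree(sk_pts)
        for i, e in enumerate(ends):
            idx = sk_tree.query_ball_point(e, r=6.0)
            local = sk_pts[idx]
            v = e - local.mean(axis=0)
            n = np.hypot(*v)
            dirs[i] = v / n if n > 0 else v
        tree = cKDTree(ends)
        pairs = sorted(tree.query_pairs(max_gap))
        bridged = False
        for i, j in pairs:
            if comp_of[i] == comp_of[j]:
                continue
            gap = ends[j] - ends[i]
            n = np.hypot(*gap)
            if n == 0:
                continue
            u = gap / n
            # ends must point toward each other (collinear continuation)
            if np.dot(dirs[i], u) < 0.3 or np.dot(dirs[j], -u) < 0.3:
                continue
            rr, cc = draw_line(*ends[i], *ends[j])
            out[rr, cc] = True
            # widen the 1-px bridge so skeletonization stays stable
            out[np.clip(rr + 1, 0, out.shape[0] - 1), cc] = True
            out[rr, np.clip(cc + 1, 0, out.shape[1] - 1)] = True
            bridged = True
        if not bridged:
            break
    return out


def _reconstruct(seeds: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Keep the connected components of ``mask`` that contain a seed pixel."""
    if not seeds.any():
        return np.zeros_like(mask)
    lab = cc_label(mask, connectivity=2)
    keep = np.unique(lab[seeds])
    keep = keep[keep > 0]
    return np.isin(lab, keep)


def default_min_area_px(
    pixel_size_nm: float,
    bp_per_nm: float = 2.94,
    footprint_bp: float = 50.0,
    tip_radius_nm: float = 5.0,
) -> int:
    """Speck-removal area: footprint of ~50 bp of tip-broadened backbone."""
    length_px = (footprint_bp / bp_per_nm) / pixel_size_nm
    width_px = 2.0 * tip_radius_nm / pixel_size_nm + 1.0
    return max(4, int(round(length_px * width_px)))


def stitch(frames: Sequence[HeightImage]) -> HeightImage:
    """Composite overlapping frames using their known origins.

    Frames must share ``pixel_size_nm``; origins must be (near-)integer pixel
    multiples. Overlap regions are averaged; uncovered pixels of the union
    bounding box are 0.
    """
    if not frames:
        raise ValueError("no frames to stitch")
    if len(frames) == 1:
        return frames[0].copy_with(frames[0].heights.copy())
    ps = frames[0].pixel_size_nm
    for f in frames:
        if abs(f.pixel_size_nm - ps) > 1e-9 * ps:
            raise ValueError(
                f"mismatched pixel sizes: {f.pixel_size_nm} vs {ps} nm/px"
            )
    offsets = []
    for f in frames:
        off = (f.origin_nm[0] / ps, f.origin_nm[1] / ps)
        offsets.append((int(round(off[1])), int(round(off[0]))))  # (row, col)
    rows0 = min(o[0] for o in offsets)
    cols0 = min(o[1] for o in offsets)
    rows1 = max(o[0] + f.heights.shape[0] for o, f in zip(offsets, frames))
    cols1 = max(o[1] + f.heights.shape[1] for o, f in zip(offsets, frames))
    total = np.zeros((rows1 - rows0, cols1 - cols0), dtype=float)
    count = np.zeros_like(total)
    for off, f in zip(offsets, frames):
        r, c = off[0] - rows0, off[1] - cols0
        h, w = f.heights.shape
        total[r : r + h, c : c + w] += f.heights
        count[r : r + h, c : c + w] += 1.0
    with np.errstate(invalid="ignore"):
        composite = np.where(count > 0, total / np.maximum(count, 1.0), 0.0)
    meta = dict(frames[0].metadata)
    meta["stitched_from"] = len(frames)
    return HeightImage(composite, ps, (cols0 * ps, rows0 * ps), meta)
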