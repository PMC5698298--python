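"""Synthetic AFM frame generator for surface-deposited, labeled DNA.

Produces ground-truthed height images: 2D worm-like-chain backbones rendered
as low ridges, bound protein labels as taller Gaussian bumps, tip-convolution
broadening, per-scan-line offsets, and pixel noise. Also provides a
measurement-level ladder sampler for sizing statistics that do not need the
imaging stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from nanomap.imageproc import HeightImage


class RenderError(RuntimeError):
    """Raised when molecules cannot be placed into the requested frame."""


@dataclass(frozen=True)
class SimConfig:
    """Physical and instrumental parameters of the simulator.

    ``heading_limit_rad`` optionally bounds the chain heading around its
    initial direction (reflecting boundary). A limit < pi/2 makes the path
    monotone along its initial axis, hence self-avoiding — a stand-in for
    flow-elongated deposition of long molecules. ``None`` gives the free 2D
    worm-like chain.
    """

    bp_per_nm: float = 2.94
    persistence_length_nm: float = 50.0
    pixel_size_nm: float = 2.5
    frame_size_px: tuple[int, int] = (1000, 1000)
    tip_radius_nm: float = 5.0
    dna_height_nm: float = 0.3
    label_height_nm: float = 3.0
    label_footprint_nm: float = 8.0
    noise_sd_nm: float = 0.1
    line_offset_sd_nm: float = 0.1
    labeling_efficiency: float = 0.9
    mismatch_efficiency: float = 0.5
    off_target_rate: float = 0.0
    seed: int = 0
    heading_limit_rad: float | None = None

    def __post_init__(self) -> None:
        positive = {
            "bp_per_nm": self.bp_per_nm,
            "persistence_length_nm": self.persistence_length_nm,
            "pixel_size_nm": self.pixel_size_nm,
            "tip_radius_nm": self.tip_radius_nm,
            "dna_height_nm": self.dna_height_nm,
            "label_height_nm": self.label_height_nm,
            "label_footprint_nm": self.label_footprint_nm,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        for name, value in (
            ("noise_sd_nm", self.noise_sd_nm),
            ("line_offset_sd_nm", self.line_offset_sd_nm),
            ("off_target_rate", self.off_target_rate),
        ):
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        for name, value in (
            ("labeling_efficiency", self.labeling_efficiency),
            ("mismatch_efficiency", self.mismatch_efficiency),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if len(self.frame_size_px) != 2 or any(s < 8 for s in self.frame_size_px):
            raise ValueError(f"frame_size_px must be two sizes >= 8, got {self.frame_size_px}")
        if self.heading_limit_rad is not None and not 0 < self.heading_limit_rad <= math.pi:
            raise ValueError("heading_limit_rad must be in (0, pi] or None")

    def rng(self) -> np.random.Generator:
        """Root generator for this configuration's seed."""
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class TruthLabel:
    """Ground-truth label site on a simulated molecule."""

    position_bp: float
    kind: str  # perfect | mismatch | off_target
    bound: bool

    def __post_init__(self) -> None:
        if self.kind not in ("perfect", "mismatch", "off_target"):
            raise ValueError(f"unknown label kind {self.kind!r}")


@dataclass
class SimMolecule:
    """A simulated molecule: conformation plus ground-truth labels."""

    id: str
    length_bp: int
    path: np.ndarray  # (n, 2) nm coordinates, ordered along the contour
    truth_labels: list[TruthLabel] = field(default_factory=list)

    def arc_length_nm(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.path, axis=0).T)))


@dataclass(frozen=True)
class Placement:
    """Rigid placement of a molecule inside a frame (nm coordinates)."""

    offset_nm: tuple[float, float]
    rotation_rad: float


@dataclass
class FrameTruth:
    """Per-frame ground truth: one record per molecule and per label.

    ``table`` columns: frame, molecule_id, length_bp, contour_nm,
    label_kind, label_pos_bp, label_arc_nm, bound. Molecules without bound
    labels contribute a single row with NA label fields.
    """

    frame_id: str
    table: pd.DataFrame
    placements: dict[str, Placement] = field(default_factory=dict)

    def molecule_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["molecule_id"]))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def sample_wlc_chain(
    length_bp: int,
    cfg: SimConfig,
    rng: np.random.Generator,
    heading_limit_rad: float | None = None,
) -> np.ndarray:
    """Sample a discrete 2D worm-like chain conformation.

    Headings perform a Gaussian random walk with per-step variance
    ``step/persistence_length``, giving the 2D surface-equilibrated tangent
    correlation ``exp(-s / (2 * lp))``. Returns an ``(n+1, 2)`` array of nm
    coordinates whose polyline arc length equals ``length_bp / bp_per_nm``
    exactly (up to float rounding).
    """
    if length_bp < 1:
        raise ValueError(f"length_bp must be >= 1, got {length_bp}")
    if heading_limit_rad is None:
        heading_limit_rad = cfg.heading_limit_rad
    contour_nm = length_bp / cfg.bp_per_nm
    step = min(cfg.pixel_size_nm, contour_nm)
    n = max(1, int(round(contour_nm / step)))
    ds = contour_nm / n
    theta0 = rng.uniform(0.0, 2.0 * math.pi)
    increments = rng.normal(0.0, math.sqrt(ds / cfg.persistence_length_nm), size=n)
    increments[0] = 0.0  # first tangent defines the initial heading
    if heading_limit_rad is None:
        theta = theta0 + np.cumsum(increments)
    else:
        # Reflecting boundary keeps |theta - theta0| <= limit.
        dev = np.cumsum(increments)
        lim = heading_limit_rad
        dev = np.abs((dev + lim) % (4.0 * lim) - 2.0 * lim) - lim
        theta = theta0 + dev
    deltas = np.column_stack((np.cos(theta), np.sin(theta))) * ds
    path = np.vstack((np.zeros(2), np.cumsum(deltas, axis=0)))
    return path


def apply_labels(mol: SimMolecule, refmap, cfg: SimConfig, rng: np.random.Generator) -> SimMolecule:
    """Draw label occupancy for a molecule given a reference map.

    Perfect-match sites bind with probability ``labeling_efficiency``,
    single-mismatch sites with ``mismatch_efficiency``; a
    Poisson(``off_target_rate``) number of off-target labels is placed
    uniformly along the molecule. Returns a new molecule; the input is not
    modified.
    """
    if refmap.length_bp != mol.length_bp:
        raise ValueError(
            f"map length {refmap.length_bp} bp != molecule length {mol.length_bp} bp"
        )
    labels: list[TruthLabel] = []
    for site in refmap.sites:
        eff = (
            cfg.labeling_efficiency
            if site.match_type == "perfect"
            else cfg.mismatch_efficiency
        )
        bound = bool(rng.random() < eff)
        labels.append(TruthLabel(float(site.pos_bp), site.match_type, bound))
    n_off = int(rng.poisson(cfg.off_target_rate))
    for _ in range(n_off):
        pos = float(rng.uniform(1.0, mol.length_bp))
        labels.append(TruthLabel(pos, "off_target", True))
    labels.sort(key=lambda lb: lb.position_bp)
    return SimMolecule(mol.id, mol.length_bp, mol.path, labels)


def _cumulative_arc(path: np.ndarray) -> np.ndarray:
    seg = np.hypot(*np.diff(path, axis=0).T)
    return np.concatenate(([0.0], np.cumsum(seg)))


def _point_at_arc(path: np.ndarray, arc: np.ndarray, s) -> np.ndarray:
    s = np.atleast_1d(np.clip(s, 0.0, arc[-1]))
    x = np.interp(s, arc, path[:, 0])
    y = np.interp(s, arc, path[:, 1])
    return np.column_stack((x, y))


def _densify(path: np.ndarray, spacing_nm: float) -> np.ndarray:
    arc = _cumulative_arc(path)
    n = max(2, int(math.ceil(arc[-1] / spacing_nm)) + 1)
    return _point_at_arc(path, arc, np.linspace(0.0, arc[-1], n))


def _tip_sag_nm(d_nm: np.ndarray, tip_radius_nm: float) -> np.ndarray:
    """Height drop of a spherical tip cap at lateral distance ``d`` from the
    contact apex (non-negative; +inf outside the tip radius)."""
    d = np.asarray(d_nm, dtype=float)
    r2 = tip_radius_nm**2
    with np.errstate(invalid="ignore"):
        sag = tip_radius_nm - np.sqrt(np.maximum(r2 - d * d, 0.0))
    return np.where(d <= tip_radius_nm, sag, np.inf)


def _dilated_bump_profile(cfg: SimConfig, step_nm: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Radial height profile of a Gaussian label bump imaged by a spherical
    tip: grayscale dilation of the bump with the tip cap, computed exactly in
    1D thanks to radial symmetry."""
    sigma = cfg.label_footprint_nm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    support = 4.0 * sigma + cfg.tip_radius_nm
    r = np.arange(0.0, support + step_nm, step_nm)
    u = r.copy()
    bump_u = cfg.label_height_nm * np.exp(-(u**2) / (2.0 * sigma**2))
    # max over source offsets u of bump(u) - sag(|r - u|)
    sag = _tip_sag_nm(np.abs(r[:, None] - u[None, :]), cfg.tip_radius_nm)
    prof = np.max(bump_u[None, :] - sag, axis=1)
    return r, np.maximum(prof, 0.0)


def _transform(path: np.ndarray, placement: Placement) -> np.ndarray:
    c, s = math.cos(placement.rotation_rad), math.sin(placement.rotation_rad)
    rot = np.array([[c, -s], [s, c]])
    rel = path - path[0]
    return rel @ rot.T + np.asarray(placement.offset_nm)


def _rasterize_molecule(
    img: np.ndarray,
    mol: SimMolecule,
    placed: np.ndarray,
    cfg: SimConfig,
    origin_nm,
    supersample: int = 3,
) -> None:
    """Render one molecule's tip-dilated surface into ``img`` (max-composite).

    The backbone contributes ``dna_height - tip_sag(distance to path)``,
    evaluated from an exact Euclidean distance transform on a supersampled
    local grid, which keeps the ridge's apparent height independent of its
    orientation relative to the pixel lattice. Labels contribute a
    radially-symmetric dilated Gaussian bump (computed analytically).
    """
    from scipy.ndimage import distance_transform_edt

    h, w = img.shape
    ps = cfg.pixel_size_nm
    band_nm = math.sqrt(max(2.0 * cfg.tip_radius_nm * cfg.dna_height_nm - cfg.dna_height_nm**2, 0.0))

    # local coarse-pixel window around the molecule
    lo = placed.min(axis=0)
    hi = placed.max(axis=0)
    pad = band_nm + 2 * ps
    c0 = max(0, int(math.floor((lo[0] - origin_nm[0] - pad) / ps)))
    r0 = max(0, int(math.floor((lo[1] - origin_nm[1] - pad) / ps)))
    c1 = min(w, int(math.ceil((hi[0] - origin_nm[0] + pad) / ps)) + 1)
    r1 = min(h, int(math.ceil((hi[1] - origin_nm[1] + pad) / ps)) + 1)
    if r0 >= r1 or c0 >= c1:
        return

    # fine grid aligned so that fine index ``off`` coincides with the coarse
    # pixel center (coarse pixel i has coordinate i * ps)
    fine_ps = ps / supersample
    off = supersample // 2
    fh, fw = (r1 - r0) * supersample, (c1 - c0) * supersample
    painted = np.zeros((fh, fw), dtype=bool)
    pts = _densify(placed, 0.4 * fine_ps)
    fc = np.round((pts[:, 0] - origin_nm[0] - c0 * ps) / fine_ps).astype(int) + off
    fr = np.round((pts[:, 1] - origin_nm[1] - r0 * ps) / fine_ps).astype(int) + off
    ok = (fr >= 0) & (fr < fh) & (fc >= 0) & (fc < fw)
    painted[fr[ok], fc[ok]] = True
    if painted.any():
        d_nm = distance_transform_edt(~painted, sampling=fine_ps)
        sag = _tip_sag_nm(d_nm, cfg.tip_radius_nm)
        with np.errstate(invalid="ignore"):
            surface_fine = np.maximum(cfg.dna_height_nm - sag, 0.0)
        tile = surface_fine[off::supersample, off::supersample]
        tile = tile[: r1 - r0, : c1 - c0]
        region = img[r0 : r0 + tile.shape[0], c0 : c0 + tile.shape[1]]
        np.maximum(region, tile, out=region)

    arc = _cumulative_arc(placed)
    r_prof, prof = _dilated_bump_profile(cfg)
    half = int(math.ceil(r_prof[-1] / ps)) + 1
    for lab in mol.truth_labels:
        if not lab.bound:
            continue
        center = _point_at_arc(placed, arc, lab.position_bp / cfg.bp_per_nm)[0]
        # snap bump apex to the nearest pixel so the rendered peak height is
        # exactly label_height_nm (sub-pixel apex placement is below the
        # localization scale of interest)
        cc = int(round((center[0] - origin_nm[0]) / ps))
        cr = int(round((center[1] - origin_nm[1]) / ps))
        rr0, rr1 = max(0, cr - half), min(h, cr + half + 1)
        cc0, cc1 = max(0, cc - half), min(w, cc + half + 1)
        if rr0 >= rr1 or cc0 >= cc1:
            continue
        rr = np.arange(rr0, rr1) - cr
        cc_ax = np.arange(cc0, cc1) - cc
        d_nm = np.hypot(rr[:, None], cc_ax[None, :]) * ps
        bump = np.interp(d_nm, r_prof, prof, right=0.0)
        img[rr0:rr1, cc0:cc1] = np.maximum(img[rr0:rr1, cc0:cc1], bump)


def _auto_place(
    mol_paths: Sequence[np.ndarray],
    cfg: SimConfig,
    rng: np.random.Generator,
    frame_nm: tuple[float, float],
    margin_nm: float,
    max_tries: int = 200,
) -> list[Placement]:
    """Rejection-sample non-overlapping rigid placements inside the frame."""
    ps = cfg.pixel_size_nm
    h_px = int(math.ceil(frame_nm[1] / ps))
    w_px = int(math.ceil(frame_nm[0] / ps))
    occupied = np.zeros((h_px, w_px), dtype=bool)
    margin_px = max(1, int(math.ceil(margin_nm / ps)))
    placements: list[Placement] = []
    for path in mol_paths:
        placed_ok = False
        for _ in range(max_tries):
            rot = rng.uniform(0.0, 2.0 * math.pi)
            cand = _transform(path, Placement((0.0, 0.0), rot))
            lo = cand.min(axis=0)
            hi = cand.max(axis=0)
            span = hi - lo
            free_x = frame_nm[0] - 2 * margin_nm - span[0]
            free_y = frame_nm[1] - 2 * margin_nm - span[1]
            if free_x < 0 or free_y < 0:
                continue
            off = (
                margin_nm - lo[0] + rng.uniform(0.0, free_x),
                margin_nm - lo[1] + rng.uniform(0.0, free_y),
            )
            cand = _transform(path, Placement(tuple(off), rot))
            pts = _densify(cand, 0.5 * ps)
            cols = np.clip(np.round(pts[:, 0] / ps).astype(int), 0, w_px - 1)
            rows = np.clip(np.round(pts[:, 1] / ps).astype(int), 0, h_px - 1)
            r0 = np.clip(rows - margin_px, 0, h_px)
            r1 = np.clip(rows + margin_px + 1, 0, h_px)
            c0 = np.clip(cols - margin_px, 0, w_px)
            c1 = np.clip(cols + margin_px + 1, 0, w_px)
            if any(occupied[a:b, c:d].any() for a, b, c, d in zip(r0, r1, c0, c1)):
                continue
            for a, b, c, d in zip(r0, r1, c0, c1):
                occupied[a:b, c:d] = True
            placements.append(Placement(tuple(off), rot))
            placed_ok = True
            break
        if not placed_ok:
            raise RenderError(
                "could not place molecule without overlap; "
                "reduce molecule count/length or enlarge frame"
            )
    return placements


def render_frame(
    mols: Sequence[SimMolecule],
    cfg: SimConfig,
    rng: np.random.Generator,
    placements: Sequence[Placement] | None = None,
    origin_nm: tuple[float, float] = (0.0, 0.0),
    frame_size_px: tuple[int, int] | None = None,
    frame_id: str = "frame0",
    auto_size: bool = False,
) -> tuple[HeightImage, FrameTruth]:
    """Render molecules into a height image and return it with ground truth.

    Rendering order: rasterize backbones at ``dna_height_nm``; add Gaussian
    label bumps peaking at ``label_height_nm``; grayscale-dilate with a
    spherical tip cap of ``tip_radius_nm``; add per-scan-line offsets; add
    i.i.d. pixel noise. With ``placements=None``, placements are
    rejection-sampled to be non-overlapping. ``auto_size=True`` sizes the
    frame to fit the molecules (single-molecule convenience mode).
    """
    size = tuple(frame_size_px) if frame_size_px is not None else tuple(cfg.frame_size_px)
    ps = cfg.pixel_size_nm
    # separation margin: comfortably above the segmentation gap-bridging
    # radius so distinct molecules can never be linked
    margin_nm = 4.0 * cfg.tip_radius_nm + 8.0 * ps

    if auto_size:
        if placements is None:
            spans = []
            for m in mols:
                rel = m.path - m.path[0]
                spans.append(np.ptp(rel, axis=0))
            # place molecules side by side along y in their sampled pose
            widths = [sp[0] + 2 * margin_nm for sp in spans]
            heights = [sp[1] + 2 * margin_nm for sp in spans]
            w_nm = max(widths) if widths else 50 * ps
            h_nm = float(np.sum(heights)) if heights else 50 * ps
            placements = []
            y0 = 0.0
            for m, sp in zip(mols, spans):
                rel = m.path - m.path[0]
                lo = rel.min(axis=0)
                placements.append(Placement((margin_nm - lo[0], y0 + margin_nm - lo[1]), 0.0))
                y0 += sp[1] + 2 * margin_nm
            size = (int(math.ceil(h_nm / ps)), int(math.ceil(w_nm / ps)))
        else:
            raise ValueError("auto_size requires placements=None")
    h_px, w_px = int(size[0]), int(size[1])
    frame_nm = (w_px * ps, h_px * ps)

    diag_nm = math.hypot(*frame_nm) - 2 * margin_nm
    for m in mols:
        if m.arc_length_nm() > 0 and np.ptp(m.path, axis=0).max() > diag_nm:
            raise RenderError(
                f"molecule {m.id} ({m.arc_length_nm():.0f} nm) does not fit the "
                "frame; render multi-frame or enlarge frame_size_px"
            )

    if placements is None:
        placements = _auto_place([m.path for m in mols], cfg, rng, frame_nm, margin_nm)
    if len(placements) != len(mols):
        raise ValueError("one placement per molecule required")

    img = np.zeros((h_px, w_px), dtype=float)
    records = []
    placement_map: dict[str, Placement] = {}
    for mol, plc in zip(mols, placements):
        placed = _transform(mol.path, plc)
        _rasterize_molecule(img, mol, placed, cfg, origin_nm)
        placement_map[mol.id] = plc
        contour = float(np.sum(np.hypot(*np.diff(placed, axis=0).T)))
        bound = [lab for lab in mol.truth_labels if lab.bound]
        if not bound:
            records.append(
                dict(
                    frame=frame_id,
                    molecule_id=mol.id,
                    length_bp=mol.length_bp,
                    contour_nm=contour,
                    label_kind=pd.NA,
                    label_pos_bp=np.nan,
                    label_arc_nm=np.nan,
                    bound=pd.NA,
                )
            )
        for lab in mol.truth_labels:
            records.append(
                dict(
                    frame=frame_id,
                    molecule_id=mol.id,
                    length_bp=mol.length_bp,
                    contour_nm=contour,
                    label_kind=lab.kind,
                    label_pos_bp=lab.position_bp,
                    label_arc_nm=lab.position_bp / cfg.bp_per_nm,
                    bound=lab.bound,
                )
            )

    if cfg.line_offset_sd_nm > 0:
        img += rng.normal(0.0, cfg.line_offset_sd_nm, size=(h_px, 1))
    if cfg.noise_sd_nm > 0:
        img += rng.normal(0.0, cfg.noise_sd_nm, size=img.shape)

    truth = FrameTruth(
        frame_id,
        pd.DataFrame(
            records,
            columns=[
                "frame",
                "molecule_id",
                "length_bp",
                "contour_nm",
                "label_kind",
                "label_pos_bp",
                "label_arc_nm",
                "bound",
            ],
        ),
        placement_map,
    )
    height_img = HeightImage(
        heights=img,
        pixel_size_nm=ps,
        origin_nm=tuple(origin_nm),
        metadata={"frame_id": frame_id, "synthetic": True},
    )
    return height_img, truth


def make_ladder_sample(
    lengths_bp: Sequence[float],
    n_per: int,
    sizing_sd_bp: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Measurement-level ladder sample: per-molecule sizes ~ N(true, sd).

    Returns a table with columns ``species_bp`` (true length) and
    ``measured_bp`` (one row per simulated molecule).
    """
    lengths = list(lengths_bp)
    if not lengths:
        raise ValueError("lengths_bp must be non-empty")
    if n_per < 1:
        raise ValueError(f"n_per must be >= 1, got {n_per}")
    if sizing_sd_bp < 0:
        raise ValueError(f"sizing_sd_bp must be >= 0, got {sizing_sd_bp}")
    frames = []
    for true_bp in lengths:
        measured = true_bp + rng.normal(0.0, sizing_sd_bp, size=n_per) if sizing_sd_bp > 0 else np.full(n_per, float(true_bp))
        frames.append(pd.DataFrame({"species_bp": float(true_bp), "measured_bp": measured}))
    return pd.concat(frames, ignore_index=True)


def simulate_molecule(
    mol_id: str,
    length_bp: int,
    cfg: SimConfig,
    rng: np.random.Generator,
    refmap=None,
    heading_limit_rad: float | None = None,
) -> SimMolecule:
    """Convenience: sample a conformation and (optionally) draw labels."""
    path = sample_wlc_chain(length_bp, cfg, rng, heading_limit_rad=heading_limit_rad)
    mol = SimMolecule(mol_id, length_bp, path)
    if refmap is not None:
        mol = apply_labels(mol, refmap, cfg, rng)
    return mol


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Return a copy of ``cfg`` with a different seed."""
    return replace(cfg, seed=seed)
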