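"""Label calling: sample the image along a traced backbone and detect bound
protein labels as height excursions; report arc positions from endpoint A."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import interpolate
from scipy.ndimage import map_coordinates, maximum_filter
from scipy.signal import find_peaks

from nanomap.calibration import Calibration
from nanomap.imageproc import HeightImage
from nanomap.tracing import MoleculeTrace, TraceError


@dataclass(frozen=True)
class DetectConfig:
    prominence_nm: float = 1.0
    min_sep_nm: float = 10.0
    sampling_step_nm: float | None = None  # default: pixel_size / 2
    normal_halfwidth_px: float = 1.0
    merge_width_factor: float = 1.8  # width above this multiple of expected -> merged
    expected_width_nm: float | None = None


@dataclass
class BackboneProfile:
    """Height sampled along the backbone at (near-)uniform arc spacing."""

    arc_nm: np.ndarray
    height_nm: np.ndarray

    def __post_init__(self) -> None:
        if len(self.arc_nm) != len(self.height_nm):
            raise ValueError("arc and height arrays must align")
        if len(self.arc_nm) and self.arc_nm[0] != 0.0:
            raise ValueError("profile must start at arc position 0")

    @property
    def length_nm(self) -> float:
        return float(self.arc_nm[-1])

    def reversed(self) -> "BackboneProfile":
        rev_arc = self.arc_nm[-1] - self.arc_nm[::-1]
        return BackboneProfile(rev_arc, self.height_nm[::-1].copy())


@dataclass(frozen=True)
class LabelCall:
    arc_pos_nm: float
    prominence_nm: float
    width_nm: float
    merged: bool = False


@dataclass
class MoleculeMeasurement:
    """One molecule's measured contour and ordered label calls."""

    trace: MoleculeTrace
    labels: list[LabelCall]
    contour_length_nm: float
    contour_length_bp: float
    orientation: str = "unresolved"  # unresolved | A-first | B-first
    molecule_id: str | None = None

    def label_positions_nm(self) -> np.ndarray:
        return np.array([lb.arc_pos_nm for lb in self.labels])

    def label_positions_bp(self, cal: Calibration | None = None) -> np.ndarray:
        cal = cal or Calibration()
        return self.label_positions_nm() * cal.bp_per_nm


def _uniform_arc_samples(trace: MoleculeTrace, step_nm: float) -> tuple[np.ndarray, np.ndarray]:
    """Invert the spline's arc-length function to sample at uniform arc steps."""
    tck = trace.spline
    fine = max(1024, 8 * len(trace.backbone_nm))
    u = np.linspace(0.0, 1.0, fine)
    x, y = interpolate.splev(u, tck)
    seg = np.hypot(np.diff(x), np.diff(y))
    arc = np.concatenate(([0.0], np.cumsum(seg)))
    total = arc[-1]
    n = max(2, int(math.ceil(total / step_nm)) + 1)
    s = np.linspace(0.0, total, n)
    u_of_s = np.interp(s, arc, u)
    return s, u_of_s


def backbone_profile(
    img: HeightImage,
    trace: MoleculeTrace,
    sampling_step_nm: float | None = None,
    normal_halfwidth_px: float = 1.0,
) -> BackboneProfile:
    """Sample image heights along the trace spline.

    Heights are bilinearly interpolated; at each arc position the maximum
    over a short window along the local normal (+/- ``normal_halfwidth_px``)
    is taken, making the profile robust to sub-pixel lateral spline error.
    """
    if trace.spline is None:
        raise TraceError("cannot profile a flagged/unfitted trace")
    step = sampling_step_nm if sampling_step_nm is not None else img.pixel_size_nm / 2.0
    length = trace.contour_length_nm
    if step > length:
        raise ValueError(f"sampling step {step} nm exceeds contour {length:.3g} nm")
    s, u = _uniform_arc_samples(trace, step)
    x, y = interpolate.splev(u, trace.spline)
    dx, dy = interpolate.splev(u, trace.spline, der=1)
    norm = np.hypot(dx, dy)
    norm[norm == 0] = 1.0
    nx_, ny_ = -dy / norm, dx / norm
    ps = img.pixel_size_nm
    ox, oy = img.origin_nm
    # 3x3 max filter closes the bilinear dips between diagonally adjacent
    # ridge pixels of a 1-px-wide backbone
    heights_img = maximum_filter(img.heights, size=3)
    # fine offsets across the ridge: a 1-px-wide backbone needs sub-pixel
    # sampling for the max to land near the true ridge height
    n_off = max(3, int(round(2 * normal_halfwidth_px / 0.125)) + 1)
    offsets_px = (
        np.linspace(-normal_halfwidth_px, normal_halfwidth_px, n_off)
        if normal_halfwidth_px > 0
        else np.array([0.0])
    )
    heights = np.full(len(s), -np.inf)
    for off in offsets_px:
        cx = (x + off * nx_ * ps - ox) / ps
        cy = (y + off * ny_ * ps - oy) / ps
        vals = map_coordinates(heights_img, [cy, cx], order=1, mode="nearest")
        heights = np.maximum(heights, vals)
    # rescale arc axis so the last sample lands exactly on the contour length
    if s[-1] > 0:
        s = s * (length / s[-1])
    return BackboneProfile(s, heights)


def detect_labels(profile: BackboneProfile, cfg: DetectConfig | None = None) -> list[LabelCall]:
    """Detect label peaks on a backbone profile.

    Peaks require prominence >= ``prominence_nm`` and mutual separation >=
    ``min_sep_nm``. The reported position is the prominence-weighted centroid
    within the full-width-at-half-prominence window (sub-pixel localization);
    width is the FWHP in nm.
    """
    cfg = cfg or DetectConfig()
    h = np.asarray(profile.height_nm, dtype=float)
    if len(h) < 3:
        return []
    step = float(np.median(np.diff(profile.arc_nm)))
    distance = max(1, int(round(cfg.min_sep_nm / step)))
    peaks, props = find_peaks(h, prominence=cfg.prominence_nm, distance=distance)
    calls: list[LabelCall] = []
    for idx, prom in zip(peaks, props["prominences"]):
        base = h[idx] - prom
        half_level = base + prom / 2.0
        lo = idx
        while lo > 0 and h[lo - 1] >= half_level:
            lo -= 1
        hi = idx
        while hi < len(h) - 1 and h[hi + 1] >= half_level:
            hi += 1
        window = slice(lo, hi + 1)
        weights = [max(v - base, 0.0) for v in h[window]]
        wsum = math.fsum(weights)
        if wsum <= 0:
            pos = float(profile.arc_nm[idx])
        else:
            pos = math.fsum(w * a for w, a in zip(weights, profile.arc_nm[window])) / wsum
        width = float(profile.arc_nm[hi] - profile.arc_nm[lo])
        expected = cfg.expected_width_nm
        merged = expected is not None and width > cfg.merge_width_factor * expected
        calls.append(LabelCall(float(pos), float(prom), width, merged))
    calls.sort(key=lambda c: c.arc_pos_nm)
    return calls


def measure_molecule(
    img: HeightImage,
    trace: MoleculeTrace,
    cfg: DetectConfig | None = None,
    cal: Calibration | None = None,
    molecule_id: str | None = None,
) -> MoleculeMeasurement:
    """Profile a trace, detect labels, and report nm/bp quantities.

    Orientation is left unresolved: positions are from endpoint A; the
    biological end assignment happens in map matching.
    """
    cfg = cfg or DetectConfig()
    cal = cal or Calibration()
    profile = backbone_profile(
        img,
        trace,
        sampling_step_nm=cfg.sampling_step_nm,
        normal_halfwidth_px=cfg.normal_halfwidth_px,
    )
    labels = detect_labels(profile, cfg)
    length_nm = float(trace.contour_length_nm)
    return MoleculeMeasurement(
        trace=trace,
        labels=labels,
        contour_length_nm=length_nm,
        contour_length_bp=cal.nm_to_bp(length_nm),
        orientation="unresolved",
        molecule_id=molecule_id,
    )
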