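"""Backbone tracing: skeletonize a component, prune to the longest
end-to-end geodesic, fit a smoothing cubic spline, and measure arc length."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import integrate, interpolate
from scipy.ndimage import uniform_filter
from skimage.morphology import skeletonize

from nanomap.imageproc import ComponentMask, HeightImage


class TraceError(RuntimeError):
    """Raised when a trace cannot provide the requested quantity."""


@dataclass(frozen=True)
class TraceConfig:
    min_path_px: int = 5
    smooth_nm: float = 0.3  # target RMS spline deviation (physical scale)
    border_px: int = 2
    spline_kind: str = "smoothing"  # or "interpolating"
    endpoint_extension: bool = True
    spur_px: float = 15.0  # off-path skeleton longer than this flags 'branched'

    def __post_init__(self) -> None:
        if self.spline_kind not in ("smoothing", "interpolating"):
            raise ValueError(f"unknown spline_kind {self.spline_kind!r}")


@dataclass
class MoleculeTrace:
    """Ordered backbone path of one molecule with its spline representation.

    ``backbone_px`` is the ordered (row, col) pixel path; ``backbone_nm`` the
    corresponding physical (x, y) coordinates. ``spline`` is a parametric
    cubic B-spline ``tck`` over u in [0, 1], or None when flagged.
    """

    component_id: int
    backbone_px: np.ndarray | None
    backbone_nm: np.ndarray | None
    spline: tuple | None
    contour_length_nm: float | None
    endpoints_nm: tuple | None
    flags: set[str] = field(default_factory=set)

    @property
    def ok(self) -> bool:
        return not self.flags and self.spline is not None


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    rows, cols = np.nonzero(skel)
    pixels = set(zip(rows.tolist(), cols.tolist()))
    for p in pixels:
        g.add_node(p)
    for r, c in pixels:
        for dr, dc in _NEIGHBORS:
            q = (r + dr, c + dc)
            if q in pixels and (r, c) < q:
                g.add_edge((r, c), q, weight=math.hypot(dr, dc))
    # 8-connected skeletons often contain spurious triangles (diagonal +
    # orthogonal shortcuts); drop diagonal edges that a 2-step orthogonal
    # route already covers so cycle detection reflects true loops only.
    for u, v in list(g.edges()):
        if abs(u[0] - v[0]) == 1 and abs(u[1] - v[1]) == 1:
            a, b = (u[0], v[1]), (v[0], u[1])
            if (g.has_node(a) and g.has_edge(u, a) and g.has_edge(a, v)) or (
                g.has_node(b) and g.has_edge(u, b) and g.has_edge(b, v)
            ):
                g.remove_edge(u, v)
    return g


def longest_geodesic(g: nx.Graph) -> tuple[list, float]:
    """Maximum-length shortest path between degree-1 nodes (graph 'diameter'
    restricted to endpoints). Falls back to all nodes when no endpoints
    exist. Deterministic tie-break by lexicographic endpoint coordinates."""
    endpoints = sorted(n for n in g.nodes if g.degree(n) == 1)
    candidates = endpoints if len(endpoints) >= 2 else sorted(g.nodes)
    best: tuple[float, tuple, tuple] | None = None
    for i, src in enumerate(candidates):
        dist, paths = nx.single_source_dijkstra(g, src, weight="weight")
        for dst in candidates[i + 1 :]:
            if dst not in dist:
                continue
            key = (dist[dst], src, dst)
            if best is None or key[0] > best[0] + 1e-9 or (
                abs(key[0] - best[0]) <= 1e-9 and (src, dst) < (best[1], best[2])
            ):
                best = key
                best_path = paths[dst]
    if best is None:
        only = candidates[0] if candidates else None
        return ([only] if only else []), 0.0
    return best_path, best[0]


def _fill_small_holes(mask: np.ndarray, max_hole_px: int = 9) -> np.ndarray:
    """Fill interior holes up to ``max_hole_px`` (closing/noise artifacts);
    large holes (true loops) are preserved."""
    from scipy.ndimage import binary_fill_holes, label as nd_label

    filled = binary_fill_holes(mask)
    holes = filled & ~mask
    if not holes.any():
        return mask
    lab, n = nd_label(holes)
    out = mask.copy()
    for i in range(1, n + 1):
        idx = lab == i
        if idx.sum() <= max_hole_px:
            out[idx] = True
    return out


def _offpath_extent(g: nx.Graph, path: list) -> float:
    """Largest graph distance (px) from the pruned path to any skeleton node."""
    on_path = set(path)
    off = set(g.nodes) - on_path
    if not off:
        return 0.0
    dist = nx.multi_source_dijkstra_path_length(g, on_path, weight="weight")
    return max((dist.get(n, float("inf")) for n in off), default=0.0)


def _fit_spline(
    points_nm: np.ndarray, pixel_size_nm: float, cfg: TraceConfig, noise_sd_nm: float = 0.0
):
    m = len(points_nm)
    k = min(3, m - 1)
    if cfg.spline_kind == "interpolating":
        s = 0.0
    else:
        # residual target: pixel quantization plus the lateral centerline
        # jitter induced by height noise on a faint ridge
        target = math.hypot(cfg.smooth_nm, 4.0 * noise_sd_nm)
        s = m * target**2
    # chord-length parameterization stabilizes the fit on curvy backbones
    seg = np.hypot(*np.diff(points_nm, axis=0).T)
    u = np.concatenate(([0.0], np.cumsum(seg)))
    if u[-1] == 0:
        raise TraceError("degenerate backbone (zero length)")
    u /= u[-1]
    tck, _ = interpolate.splprep(points_nm.T, u=u, s=s, k=k)
    return tck


def _spline_speed(tck):
    def speed(u):
        dx, dy = interpolate.splev(u, tck, der=1)
        return float(np.hypot(dx, dy))

    return speed


def _arc_length(tck, a: float = 0.0, b: float = 1.0) -> float:
    import warnings as _warnings

    with _warnings.catch_warnings():
        # long noisy splines legitimately exhaust subdivisions; the returned
        # estimate is still far more accurate than the 0.01% we need
        _warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(_spline_speed(tck), a, b, limit=200)
    return float(val)


def _local_height(smooth_img: np.ndarray, r: int, c: int) -> float:
    h, w = smooth_img.shape
    return float(smooth_img[max(0, min(r, h - 1)), max(0, min(c, w - 1))])


def _trim_low_ends(path_px: list, smooth_img: np.ndarray, ridge_nm: float, frac: float = 0.5) -> list:
    """Drop path-end pixels whose local height is well below the ridge level.

    The longest-geodesic criterion favors spur tips grown from noise pixels;
    those ends sit near the detection floor rather than at backbone height.
    """
    lo = frac * ridge_nm
    start, stop = 0, len(path_px)
    while start < stop - 2 and _local_height(smooth_img, *map(round, path_px[start])) < lo:
        start += 1
    while stop - 1 > start + 1 and _local_height(smooth_img, *map(round, path_px[stop - 1])) < lo:
        stop -= 1
    return list(path_px[start:stop])


def _extend_to_mask_edge(
    path_px: list, mask: np.ndarray, smooth_img: np.ndarray, ridge_nm: float, frac: float = 0.5
) -> list:
    """Extend each path end along its local tangent while still inside the
    component mask and at backbone-like height. Compensates the end erosion
    of morphological thinning."""
    if len(path_px) < 3:
        return path_px
    out = list(path_px)
    h, w = mask.shape
    lo = frac * ridge_nm
    for end in (0, -1):
        k = min(5, len(out) - 1)
        tip = np.asarray(out[end], dtype=float)
        inner = np.asarray(out[k] if end == 0 else out[-1 - k], dtype=float)
        direction = tip - inner
        norm = np.hypot(*direction)
        if norm == 0:
            continue
        direction /= norm
        added = []
        pos = tip.copy()
        # cap at the thinning erosion scale (~ribbon half-width) so a hooked
        # ridge end cannot pull the extension along the molecule itself
        for _ in range(6):
            pos = pos + 0.5 * direction
            r, c = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= r < h and 0 <= c < w) or not mask[r, c]:
                break
            if _local_height(smooth_img, r, c) < lo:
                break
            if added and np.allclose(added[-1], pos):
                continue
            added.append(pos.copy())
        if not added:
            continue
        if end == 0:
            out = [tuple(p) for p in reversed(added)] + out
        else:
            out = out + [tuple(p) for p in added]
    return out


def trace_molecule(
    comp: ComponentMask,
    comp_id: int,
    img: HeightImage,
    cfg: TraceConfig | None = None,
) -> MoleculeTrace:
    """Reduce one segmented component to a backbone trace.

    Skeletonizes the component, prunes side branches to the longest
    end-to-end geodesic path, fits a cubic (smoothing) spline in nm
    coordinates, and sets quality flags: ``branched`` (junction present),
    ``looped`` (skeleton cycle), ``edge_clipped`` (near the frame border),
    ``too_short`` (not enough backbone to fit).
    """
    cfg = cfg or TraceConfig()
    mask = _fill_small_holes(comp.mask_of(comp_id))
    flags: set[str] = set()
    if mask.sum() < cfg.min_path_px:
        return MoleculeTrace(comp_id, None, None, None, None, None, {"too_short"})

    skel = skeletonize(mask)
    g = _skeleton_graph(skel)
    if g.number_of_nodes() == 0:
        return MoleculeTrace(comp_id, None, None, None, None, None, {"too_short"})

    # cycles longer than a noise-artifact scale mean a genuinely looped or
    # self-crossing molecule
    for cycle in nx.cycle_basis(g):
        perimeter = len(cycle)
        if perimeter > max(8, int(2 * cfg.spur_px)):
            flags.add("looped")
            break

    rows, cols = np.nonzero(skel)
    if (
        rows.min() < cfg.border_px
        or cols.min() < cfg.border_px
        or rows.max() >= mask.shape[0] - cfg.border_px
        or cols.max() >= mask.shape[1] - cfg.border_px
    ):
        flags.add("edge_clipped")

    if "looped" in flags:
        return MoleculeTrace(comp_id, None, None, None, None, None, flags)

    path, _ = longest_geodesic(g)
    if len(path) < cfg.min_path_px:
        flags.add("too_short")
        return MoleculeTrace(comp_id, None, None, None, None, None, flags)

    # substantial skeleton material off the pruned path means a real branch
    # (e.g., crossing molecules); short spurs are thinning noise. The noise
    # allowance grows (capped) with path length.
    spur_thresh = max(cfg.spur_px, min(30.0, 0.02 * len(path)))
    if _offpath_extent(g, path) > spur_thresh:
        flags.add("branched")

    smooth_img = uniform_filter(img.heights, size=3)
    interior = [p for p in path[2:-2]] or path
    ridge_nm = float(np.median([_local_height(smooth_img, *p) for p in interior]))
    path = _trim_low_ends(path, smooth_img, ridge_nm)
    if len(path) < cfg.min_path_px:
        flags.add("too_short")
        return MoleculeTrace(comp_id, None, None, None, None, None, flags)
    if cfg.endpoint_extension:
        path = _extend_to_mask_edge(path, mask, smooth_img, ridge_nm)

    path_px = np.asarray(path, dtype=float)
    # endpoint A = lexicographically smaller pixel coordinate
    if tuple(path_px[-1]) < tuple(path_px[0]):
        path_px = path_px[::-1]

    ps = img.pixel_size_nm
    ox, oy = img.origin_nm
    backbone_nm = np.column_stack((path_px[:, 1] * ps + ox, path_px[:, 0] * ps + oy))
    med = float(np.median(img.heights))
    noise_sd = 1.4826 * float(np.median(np.abs(img.heights - med)))
    try:
        tck = _fit_spline(backbone_nm, ps, cfg, noise_sd_nm=noise_sd)
    except (TraceError, TypeError, ValueError):
        flags.add("too_short")
        return MoleculeTrace(comp_id, path_px, backbone_nm, None, None, None, flags)
    length = _arc_length(tck)
    ends = (
        tuple(float(v) for v in np.asarray(interpolate.splev(0.0, tck))),
        tuple(float(v) for v in np.asarray(interpolate.splev(1.0, tck))),
    )
    return MoleculeTrace(comp_id, path_px, backbone_nm, tck, length, ends, flags)


def contour_length(trace: MoleculeTrace) -> float:
    """Arc length of the trace spline by adaptive quadrature (nm)."""
    if trace.spline is None:
        raise TraceError(
            f"component {trace.component_id}: no spline (flags={sorted(trace.flags)})"
        )
    return _arc_length(trace.spline)


def quality_flags(trace: MoleculeTrace, comp: ComponentMask | None = None, img: HeightImage | None = None) -> set[str]:
    """Quality flags of a trace. Only unflagged molecules should proceed to
    label calling; flagged ones are excluded rather than hand-corrected."""
    return set(trace.flags)


def arc_positions(trace: MoleculeTrace, n: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Sample the spline uniformly in parameter and return (u, cumulative arc)."""
    if trace.spline is None:
        raise TraceError("no spline on trace")
    u = np.linspace(0.0, 1.0, n)
    x, y = interpolate.splev(u, trace.spline)
    seg = np.hypot(np.diff(x), np.diff(y))
    return u, np.concatenate(([0.0], np.cumsum(seg)))
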