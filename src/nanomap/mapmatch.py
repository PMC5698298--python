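"""Reference label maps and single-molecule map matching.

Builds expected-site maps (directly or by scanning a sequence for guide
matches with an adjacent PAM), resolves molecule orientation by comparing
label patterns against the map in both directions, assigns labels to sites by
optimal one-to-one matching, and calls translocations from hybrid
prefix/suffix label patterns of two partner maps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from nanomap.calibration import Calibration

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


class MapLengthError(ValueError):
    """Molecule length incompatible with the reference map."""


@dataclass(frozen=True)
class Site:
    pos_bp: int  # 1-based center of the 20-bp protospacer
    match_type: str  # perfect | mismatch
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.match_type not in ("perfect", "mismatch"):
            raise ValueError(f"unknown match_type {self.match_type!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class ReferenceMap:
    """Expected label-site map of a locus."""

    name: str
    length_bp: int
    sites: list[Site]

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError("length_bp must be >= 1")
        self.sites = sorted(self.sites, key=lambda s: s.pos_bp)
        for s in self.sites:
            if not 1 <= s.pos_bp <= self.length_bp:
                raise ValueError(f"site {s.pos_bp} outside [1, {self.length_bp}]")

    def site_positions(self) -> np.ndarray:
        return np.array([s.pos_bp for s in self.sites], dtype=float)

    def reversed(self) -> "ReferenceMap":
        rev = [
            Site(self.length_bp - s.pos_bp + 1, s.match_type, "-" if s.strand == "+" else "+")
            for s in self.sites
        ]
        return ReferenceMap(self.name, self.length_bp, rev)

    def to_tsv(self, path) -> None:
        rows = [
            dict(name=self.name, length_bp=self.length_bp, site_pos_bp=s.pos_bp,
                 match_type=s.match_type, strand=s.strand)
            for s in self.sites
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ReferenceMap":
        tab = pd.read_csv(path, sep="\t")
        required = {"name", "length_bp", "site_pos_bp", "match_type"}
        if not required.issubset(tab.columns):
            raise ValueError(f"map TSV must have columns {sorted(required)}")
        names = tab["name"].unique()
        if len(names) != 1:
            raise ValueError("one map per TSV file expected")
        sites = [
            Site(int(r.site_pos_bp), str(r.match_type), getattr(r, "strand", "+") or "+")
            for r in tab.itertuples()
        ]
        return cls(str(names[0]), int(tab["length_bp"].iloc[0]), sites)


@dataclass(frozen=True)
class GuideSite:
    pos_bp: int  # 1-based protospacer-center position on the forward strand
    strand: str
    mismatches: int


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _pam_matches(window: np.ndarray, pam: str) -> np.ndarray:
    """Vectorized IUPAC match of a PAM pattern over candidate windows."""
    ok = np.ones(window.shape[0], dtype=bool)
    for j, code in enumerate(pam.upper()):
        allowed = _IUPAC.get(code)
        if allowed is None:
            raise ValueError(f"bad IUPAC code {code!r} in PAM")
        col = window[:, j]
        ok &= np.isin(col, np.frombuffer(allowed.encode(), dtype=np.uint8))
    return ok


def _scan_strand(seq: str, guide: str, pam: str, max_mismatches: int) -> list[tuple[int, int]]:
    """Scan one strand; returns (0-based protospacer start, mismatch count)."""
    glen, plen = len(guide), len(pam)
    n = len(seq)
    if n < glen + plen:
        return []
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    win = np.lib.stride_tricks.sliding_window_view(arr, glen + plen)
    win_valid = np.lib.stride_tricks.sliding_window_view(valid, glen + plen).all(axis=1)
    guide_arr = np.frombuffer(guide.upper().encode(), dtype=np.uint8)
    mm = (win[:, :glen] != guide_arr).sum(axis=1)
    pam_ok = _pam_matches(win[:, glen:], pam)
    hits = np.nonzero(win_valid & pam_ok & (mm <= max_mismatches))[0]
    n_ambig = int((~valid).sum())
    if n_ambig:
        warnings.warn(
            f"{n_ambig} ambiguous base(s) in sequence; windows containing them skipped",
            RuntimeWarning,
            stacklevel=3,
        )
    return [(int(s), int(mm[s])) for s in hits]


def find_guide_sites(
    sequence: str,
    guide: str,
    pam: str = "NGG",
    max_mismatches: int = 0,
) -> list[GuideSite]:
    """Find protospacer+PAM matches of a guide on both strands.

    The PAM must match exactly (IUPAC-aware); up to ``max_mismatches``
    substitutions are allowed in the protospacer. Positions are 1-based
    protospacer centers in forward-strand coordinates. Windows containing
    ambiguous bases are skipped with a warning.
    """
    if len(guide) != 20:
        raise ValueError(f"guide must be a 20-mer, got length {len(guide)}")
    if not set(guide.upper()) <= set("ACGT"):
        raise ValueError("guide must be over A/C/G/T")
    glen = len(guide)
    sites: list[GuideSite] = []
    for start, mm in _scan_strand(sequence, guide, pam, max_mismatches):
        sites.append(GuideSite(start + glen // 2 + 1, "+", mm))  # center = start+10 1-based
    rc = _revcomp(sequence)
    n = len(sequence)
    for start, mm in _scan_strand(rc, guide, pam, max_mismatches):
        fwd_start = n - (start + glen)  # 0-based forward start of the protospacer
        sites.append(GuideSite(fwd_start + glen // 2, "-", mm))
    sites.sort(key=lambda s: (s.pos_bp, s.strand))
    return sites


def map_from_guide(name: str, sequence: str, guide: str, pam: str = "NGG", max_mismatches: int = 1) -> ReferenceMap:
    """Build a ReferenceMap by scanning a sequence for guide binding sites."""
    hits = find_guide_sites(sequence, guide, pam, max_mismatches)
    sites = [
        Site(h.pos_bp, "perfect" if h.mismatches == 0 else "mismatch", h.strand) for h in hits
    ]
    return ReferenceMap(name, len(sequence), sites)


@dataclass
class SiteAssignment:
    """Result of orienting a molecule against a map and matching labels."""

    orientation: str  # A-first | B-first | ambiguous
    site_to_label: dict[int, int]  # site index -> label index (post-orientation order)
    residuals_bp: dict[int, float]
    unassigned_labels: list[int]
    total_cost: float

    def oriented_label_positions_bp(self, meas, cal: Calibration | None = None) -> np.ndarray:
        """Label positions measured from the map's 5' end given orientation."""
        cal = cal or Calibration()
        pos = meas.label_positions_bp(cal)
        if self.orientation == "B-first":
            pos = (meas.contour_length_bp - pos)[::-1]
        return pos


def _occupancy_weight(site: Site, perfect_occ: float = 0.9, mismatch_occ: float = 0.5) -> float:
    return perfect_occ if site.match_type == "perfect" else mismatch_occ


def match_labels_to_sites(
    labels_bp: np.ndarray,
    sites: Sequence[Site],
    tol_bp: float,
    miss_penalty_bp: float | None = None,
) -> tuple[dict[int, int], dict[int, float], list[int], float]:
    """Optimal one-to-one, tolerance-gated matching of labels to sites.

    Minimizes total |residual| plus penalties for unmatched labels and for
    unmatched sites (the latter weighted by expected occupancy, so skipping a
    likely-bound perfect site costs more than skipping a mismatch site).
    Returns (site->label, site->residual, unassigned label indices, cost).
    """
    if miss_penalty_bp is None:
        miss_penalty_bp = 2.0 * tol_bp
    n_lab, n_site = len(labels_bp), len(sites)
    size = n_lab + n_site
    big = 1e9
    cost = np.full((size, size), 0.0)
    site_pos = np.array([s.pos_bp for s in sites], dtype=float)
    if n_lab and n_site:
        resid = np.abs(labels_bp[:, None] - site_pos[None, :])
        cost[:n_lab, :n_site] = np.where(resid <= tol_bp, resid, big)
    # label i unmatched -> dummy column n_site + i
    cost[:n_lab, n_site:] = big
    for i in range(n_lab):
        cost[i, n_site + i] = miss_penalty_bp
    # site j unmatched -> dummy row n_lab + j
    cost[n_lab:, :n_site] = big
    for j, s in enumerate(sites):
        cost[n_lab + j, j] = miss_penalty_bp * _occupancy_weight(s)
    rows, cols = linear_sum_assignment(cost)
    site_to_label: dict[int, int] = {}
    residuals: dict[int, float] = {}
    unassigned = []
    total = 0.0
    for r, c in zip(rows, cols):
        total += cost[r, c] if cost[r, c] < big else miss_penalty_bp * 2
        if r < n_lab and c < n_site and cost[r, c] < big:
            site_to_label[c] = r
            residuals[c] = float(labels_bp[r] - site_pos[c])
        elif r < n_lab and (c >= n_site or cost[r, c] >= big):
            unassigned.append(r)
    return site_to_label, residuals, sorted(unassigned), float(total)


def orient_and_assign(
    meas,
    refmap: ReferenceMap,
    cal: Calibration | None = None,
    tol_bp: float = 300.0,
    tie_margin_bp: float | None = None,
    max_length_mismatch: float = 0.15,
) -> SiteAssignment:
    """Resolve molecule orientation against a map and assign labels to sites.

    Both orientations are scored with the optimal tolerance-gated matching;
    the lower-cost orientation wins unless the costs differ by less than the
    tie margin (default ``tol_bp`` / 2), in which case the result is
    ``ambiguous`` (matching reported for the A-first orientation).
    """
    cal = cal or Calibration()
    if tie_margin_bp is None:
        tie_margin_bp = 0.5 * tol_bp
    if not meas.labels:
        raise ValueError("measurement has no labels to orient by")
    length_bp = meas.contour_length_bp
    if abs(length_bp - refmap.length_bp) > max_length_mismatch * refmap.length_bp:
        raise MapLengthError(
            f"molecule length {length_bp:.0f} bp incompatible with map "
            f"{refmap.name} ({refmap.length_bp} bp)"
        )
    pos_a = meas.label_positions_bp(cal)
    pos_b = (length_bp - pos_a)[::-1]
    res_a = match_labels_to_sites(pos_a, refmap.sites, tol_bp)
    res_b = match_labels_to_sites(pos_b, refmap.sites, tol_bp)
    delta = res_a[3] - res_b[3]
    if abs(delta) <= tie_margin_bp:
        orientation, chosen = "ambiguous", res_a
    elif delta < 0:
        orientation, chosen = "A-first", res_a
    else:
        orientation, chosen = "B-first", res_b
    site_to_label, residuals, unassigned, total = chosen
    return SiteAssignment(orientation, site_to_label, residuals, unassigned, total)


@dataclass
class TranslocationCall:
    partner_a: str
    partner_b: str
    called: bool
    support: int
    breakpoint_interval_a_bp: tuple[float, float] | None
    breakpoint_interval_b_bp: tuple[float, float] | None
    per_molecule: list[dict] = field(default_factory=list)


def _fit_fusion(
    labels_bp: np.ndarray,
    length_bp: float,
    map_a: ReferenceMap,
    map_b: ReferenceMap,
    tol_bp: float,
) -> tuple[float, dict] | None:
    """Best prefix-from-A / suffix-from-B partition of one orientation."""
    best = None
    n = len(labels_bp)
    dist_from_end = length_bp - labels_bp
    b_sites = list(map_b.sites)
    b_end_dist = [map_b.length_bp - s.pos_bp for s in b_sites]
    for k in range(n + 1):
        a_labels = labels_bp[:k]
        b_labels = dist_from_end[k:][::-1]  # ascending distance from molecule end
        a_match, a_res, a_un, a_cost = match_labels_to_sites(a_labels, map_a.sites, tol_bp)
        b_site_objs = [Site(int(round(d)) if d >= 1 else 1, s.match_type, s.strand)
                       for d, s in zip(b_end_dist, b_sites)]
        b_match, b_res, b_un, b_cost = match_labels_to_sites(
            np.asarray(b_labels), b_site_objs, tol_bp
        )
        if not a_match or not b_match:
            continue
        cost = a_cost + b_cost
        if best is None or cost < best[0]:
            # innermost A site: largest assigned A position
            inner_a = max(map_a.sites[j].pos_bp for j in a_match)
            # innermost B site: smallest assigned B position (closest to breakpoint)
            assigned_b_pos = [b_sites[j].pos_bp for j in b_match]
            inner_b = min(assigned_b_pos)
            best = (
                cost,
                dict(
                    split=k,
                    inner_a_bp=float(inner_a),
                    inner_b_bp=float(inner_b),
                    n_a=len(a_match),
                    n_b=len(b_match),
                ),
            )
    return best


def _best_single_map_cost(
    labels_bp: np.ndarray,
    length_bp: float,
    maps: Sequence[ReferenceMap],
    tol_bp: float,
    max_length_mismatch: float = 0.15,
) -> float:
    """Best matching cost of the whole label pattern against one intact map
    (either orientation); inf when no map is length-compatible."""
    best = math.inf
    for m in maps:
        if abs(length_bp - m.length_bp) > max_length_mismatch * m.length_bp:
            continue
        for labels in (labels_bp, (length_bp - labels_bp)[::-1]):
            *_, cost = match_labels_to_sites(np.asarray(labels), m.sites, tol_bp)
            best = min(best, cost)
    return best


def call_translocation(
    measurements: Sequence,
    map_a: ReferenceMap,
    map_b: ReferenceMap,
    cal: Calibration | None = None,
    min_support: int = 10,
    tol_bp: float = 300.0,
) -> TranslocationCall:
    """Call a translocation between two partner maps from fusion molecules.

    Each molecule's labels are partitioned into a prefix matched against
    ``map_a`` (positions from the molecule start) and a suffix matched
    against ``map_b`` (positions from the molecule end), over both
    orientations; the best-cost partition wins. The per-partner breakpoint
    interval runs from the innermost assigned site to the next expected site
    (or the map edge), intersected across supporting molecules. A call is
    emitted only when support >= ``min_support``.
    """
    cal = cal or Calibration()
    per_mol = []
    for meas in measurements:
        if not meas.labels:
            continue
        pos = meas.label_positions_bp(cal)
        length = meas.contour_length_bp
        candidates = []
        for orient, labels in (("A-first", pos), ("B-first", (length - pos)[::-1])):
            fit = _fit_fusion(np.asarray(labels), length, map_a, map_b, tol_bp)
            if fit is not None:
                candidates.append((fit[0], orient, fit[1]))
        if not candidates:
            continue
        cost, orient, info = min(candidates, key=lambda t: t[0])
        # a molecule better explained by one intact partner map alone is not
        # fusion evidence (wild-type amplicons)
        if _best_single_map_cost(pos, length, (map_a, map_b), tol_bp) <= cost:
            continue
        info = dict(info, orientation=orient, cost=cost, molecule_id=meas.molecule_id)
        per_mol.append(info)

    if not per_mol:
        return TranslocationCall(map_a.name, map_b.name, False, 0, None, None, [])

    # consensus: molecules voting for the modal (innermost A, innermost B)
    # site pair are the supporting set
    votes: dict[tuple[float, float], list[dict]] = {}
    for info in per_mol:
        votes.setdefault((info["inner_a_bp"], info["inner_b_bp"]), []).append(info)
    (inner_a, inner_b), supporters = max(votes.items(), key=lambda kv: len(kv[1]))
    support = len(supporters)

    a_pos = map_a.site_positions()
    b_pos = map_b.site_positions()
    nxt = a_pos[a_pos > inner_a]
    interval_a = (inner_a, float(nxt.min()) if nxt.size else float(map_a.length_bp))
    prev = b_pos[b_pos < inner_b]
    interval_b = (float(prev.max()) if prev.size else 1.0, inner_b)
    called = support >= min_support
    return TranslocationCall(
        map_a.name, map_b.name, called, support, interval_a, interval_b, supporters
    )
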