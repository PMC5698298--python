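import itertools
import math

import numpy as np
import pytest

from nanomap.calibration import Calibration
from nanomap.labelcall import LabelCall, MoleculeMeasurement
from nanomap.mapmatch import (
    MapLengthError,
    ReferenceMap,
    Site,
    call_translocation,
    find_guide_sites,
    map_from_guide,
    match_labels_to_sites,
    orient_and_assign,
)

CAL = Calibration()


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def naive_guide_scan(seq, guide, max_mm):
    """O(n*m) oracle: both strands, exact NGG PAM."""
    hits = []
    g = len(guide)
    for strand, s in (("+", seq), ("-", _revcomp(seq))):
        for start in range(len(s) - g - 2):
            window = s[start : start + g]
            pam = s[start + g : start + g + 3]
            if any(b not in "ACGT" for b in window + pam):
                continue
            if pam[1:] != "GG":
                continue
            mm = sum(a != b for a, b in zip(window, guide))
            if mm <= max_mm:
                if strand == "+":
                    pos = start + g // 2 + 1
                else:
                    pos = (len(seq) - (start + g)) + g // 2
                hits.append((pos, strand, mm))
    return sorted(hits)


def measurement(labels_bp, length_bp, cal=CAL):
    labels = [LabelCall(cal.bp_to_nm(p), 2.5, 8.0) for p in sorted(labels_bp)]
    return MoleculeMeasurement(
        trace=None,
        labels=labels,
        contour_length_nm=cal.bp_to_nm(length_bp),
        contour_length_bp=float(length_bp),
    )


class TestReferenceMap:
    def test_sites_sorted_and_validated(self):
        m = ReferenceMap("x", 1000, [Site(700, "perfect"), Site(100, "mismatch")])
        assert [s.pos_bp for s in m.sites] == [100, 700]
        with pytest.raises(ValueError):
            ReferenceMap("x", 100, [Site(500, "perfect")])

    def test_tsv_round_trip(self, tmp_path):
        m = ReferenceMap("bcl2", 3000, [Site(500, "perfect"), Site(800, "mismatch", "-")])
        path = tmp_path / "map.tsv"
        m.to_tsv(path)
        back = ReferenceMap.from_tsv(path)
        assert back.name == m.name
        assert back.length_bp == m.length_bp
        assert [(s.pos_bp, s.match_type, s.strand) for s in back.sites] == [
            (500, "perfect", "+"),
            (800, "mismatch", "-"),
        ]


class TestFindGuideSites:
    GUIDE = "ACGTACGTACGTACGTACGT"

    def test_single_embedded_site(self):
        seq = "T" * 50 + self.GUIDE + "AGG" + "T" * 50
        sites = find_guide_sites(seq, self.GUIDE)
        assert len(sites) == 1
        assert sites[0].mismatches == 0
        assert sites[0].strand == "+"
        assert sites[0].pos_bp == 50 + 10 + 1

    def test_single_mismatch_found_with_budget(self):
        variant = "ACGTACGTACCTACGTACGT"  # one substitution
        seq = "T" * 30 + variant + "TGG" + "T" * 30
        assert find_guide_sites(seq, self.GUIDE, max_mismatches=0) == []
        sites = find_guide_sites(seq, self.GUIDE, max_mismatches=1)
        assert len(sites) == 1 and sites[0].mismatches == 1

    def test_no_pam_no_site(self):
        seq = "T" * 30 + self.GUIDE + "ATT" + "T" * 30
        assert find_guide_sites(seq, self.GUIDE) == []

    def test_reverse_strand_site(self):
        insert = _revcomp(self.GUIDE + "AGG")
        seq = "C" * 40 + insert + "C" * 40
        sites = find_guide_sites(seq, self.GUIDE)
        assert len(sites) == 1
        assert sites[0].strand == "-"

    def test_ambiguous_bases_skipped_with_warning(self):
        seq = "T" * 30 + self.GUIDE[:10] + "N" + self.GUIDE[11:] + "AGG" + "T" * 30
        with pytest.warns(RuntimeWarning, match="ambiguous"):
            sites = find_guide_sites(seq, self.GUIDE, max_mismatches=2)
        assert sites == []

    def test_agrees_with_naive_scan_on_random_sequence(self, rng):
        guide = "".join(rng.choice(list("ACGT"), 20))
        # seed the sequence with mutated copies so there are hits to compare
        parts = []
        for _ in range(6):
            filler = "".join(rng.choice(list("ACGT"), 300))
            copy = list(guide)
            for j in rng.choice(20, size=rng.integers(0, 3), replace=False):
                copy[j] = rng.choice(list("ACGT"))
            pam = "".join(rng.choice(list("ACGT"), 1)) + "GG"
            parts.append(filler + "".join(copy) + pam)
        seq = "".join(parts) + "".join(rng.choice(list("ACGT"), 300))
        for max_mm in (0, 1, 2):
            got = sorted((s.pos_bp, s.strand, s.mismatches) for s in find_guide_sites(seq, guide, max_mismatches=max_mm))
            assert got == naive_guide_scan(seq, guide, max_mm)

    def test_map_from_guide_classifies_match_types(self):
        seq = "T" * 30 + self.GUIDE + "AGG" + "T" * 30 + "ACGTACGTACCTACGTACGT" + "AGG" + "T" * 30
        m = map_from_guide("x", seq, self.GUIDE, max_mismatches=1)
        kinds = sorted(s.match_type for s in m.sites)
        assert kinds == ["mismatch", "perfect"]


class TestOrientAndAssign:
    MAP = ReferenceMap(
        "asym", 5000, [Site(400, "perfect"), Site(1200, "perfect"), Site(4100, "perfect")]
    )

    def test_identity_assignment_cost_zero(self):
        meas = measurement([400, 1200, 4100], 5000)
        asg = orient_and_assign(meas, self.MAP, CAL)
        assert asg.orientation == "A-first"
        assert len(asg.site_to_label) == 3
        assert all(abs(r) < 1e-6 for r in asg.residuals_bp.values())

    def test_reversed_molecule_recovered(self):
        labels = sorted(5000 - p for p in [400, 1200, 4100])
        meas = measurement(labels, 5000)
        asg = orient_and_assign(meas, self.MAP, CAL)
        assert asg.orientation == "B-first"
        assert all(abs(r) < 10 for r in asg.residuals_bp.values())

    def test_palindromic_layout_ambiguous(self):
        pal = ReferenceMap("pal", 2000, [Site(500, "perfect"), Site(1500, "perfect")])
        meas = measurement([500, 1500], 2000)
        asg = orient_and_assign(meas, pal, CAL)
        assert asg.orientation == "ambiguous"

    def test_length_mismatch_rejected(self):
        meas = measurement([400], 8000)
        with pytest.raises(MapLengthError):
            orient_and_assign(meas, self.MAP, CAL)

    def test_orientation_recovery_rate(self, rng):
        # spec invariant: >= 99% on noise-free 5-perfect-site asymmetric map
        sites = [900, 2600, 5200, 8400, 12000]
        refmap = ReferenceMap("brca1", 12900, [Site(p, "perfect") for p in sites])
        correct = 0
        n = 200
        for _ in range(n):
            reverse = rng.random() < 0.5
            pos = [12900 - p for p in sites] if reverse else list(sites)
            meas = measurement(pos, 12900)
            asg = orient_and_assign(meas, refmap, CAL)
            want = "B-first" if reverse else "A-first"
            correct += asg.orientation == want
        assert correct / n >= 0.99

    def test_matcher_equals_exhaustive_minimum(self, rng):
        # oracle: enumerate all injective partial matchings (<= 6x6)
        tol = 300.0
        for trial in range(40):
            n_lab = int(rng.integers(1, 5))
            n_site = int(rng.integers(1, 5))
            labels = np.sort(rng.uniform(0, 5000, n_lab))
            sites = [
                Site(int(p), "perfect" if rng.random() < 0.7 else "mismatch")
                for p in np.sort(rng.integers(1, 5000, n_site))
            ]
            _, _, _, got = match_labels_to_sites(labels, sites, tol)

            def occupancy(s):
                return 0.9 if s.match_type == "perfect" else 0.5

            best = math.inf
            site_pen = [2 * tol * occupancy(s) for s in sites]
            for k in range(0, min(n_lab, n_site) + 1):
                for lab_idx in itertools.combinations(range(n_lab), k):
                    for site_perm in itertools.permutations(range(n_site), k):
                        cost = 0.0
                        ok = True
                        for li, si in zip(lab_idx, site_perm):
                            r = abs(labels[li] - sites[si].pos_bp)
                            if r > tol:
                                ok = False
                                break
                            cost += r
                        if not ok:
                            continue
                        cost += 2 * tol * (n_lab - k)
                        cost += sum(
                            site_pen[si] for si in range(n_site) if si not in site_perm
                        )
                        best = min(best, cost)
            assert got == pytest.approx(best, rel=1e-9)


class TestCallTranslocation:
    MAP_A = ReferenceMap("bcl2", 1500, [Site(500, "perfect"), Site(800, "perfect")])
    MAP_B = ReferenceMap("igh", 1400, [Site(1200, "perfect")])

    def _fusion_measurements(self, rng, n, noise_sd=50.0, break_a=650, break_b=400):
        out = []
        for _ in range(n):
            # fusion: map_A[1..break_a] + map_B[break_b..end]
            length = break_a + (self.MAP_B.length_bp - break_b)
            labels = []
            for s in self.MAP_A.sites:
                if s.pos_bp <= break_a:
                    labels.append(s.pos_bp + rng.normal(0, noise_sd))
            for s in self.MAP_B.sites:
                if s.pos_bp >= break_b:
                    labels.append(break_a + (s.pos_bp - break_b) + rng.normal(0, noise_sd))
            if rng.random() < 0.5:
                labels = [length - p for p in labels]
            out.append(measurement(labels, length))
        return out

    def test_fusion_call_contains_breakpoint(self, rng):
        meas = self._fusion_measurements(rng, 20)
        call = call_translocation(meas, self.MAP_A, self.MAP_B, CAL, min_support=10)
        assert call.called
        assert call.support >= 10
        lo, hi = call.breakpoint_interval_a_bp
        assert lo <= 650 <= hi
        lo_b, hi_b = call.breakpoint_interval_b_bp
        assert lo_b <= 400 <= hi_b

    def test_wild_type_molecules_no_call(self, rng):
        # molecules carrying only map_A's full pattern cannot support a fusion
        meas = [measurement([500, 800], 1500) for _ in range(20)]
        call = call_translocation(meas, self.MAP_A, self.MAP_B, CAL, min_support=10)
        # wild-type length 1500 differs from fusion; the B suffix never fits
        # distally, so support stays low and no call is emitted
        assert not call.called or call.support < 10

    def test_insufficient_support_no_call(self, rng):
        meas = self._fusion_measurements(rng, 9)
        call = call_translocation(meas, self.MAP_A, self.MAP_B, CAL, min_support=10)
        assert not call.called
        assert call.support == 9

    def test_breakpoint_interval_coverage(self, rng):
        # spec invariant: interval contains truth (per-label sd <= 100 bp,
        # support >= 10) in >= 95% of 200 reps
        hits = calls = 0
        reps = 200
        for _ in range(reps):
            meas = self._fusion_measurements(rng, 14, noise_sd=100.0)
            call = call_translocation(meas, self.MAP_A, self.MAP_B, CAL, min_support=10)
            if call.support >= 10:
                calls += 1
                lo, hi = call.breakpoint_interval_a_bp
                hits += lo <= 650 <= hi
        assert calls >= 0.8 * reps  # consensus support is routinely reached
        assert hits / calls >= 0.95
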