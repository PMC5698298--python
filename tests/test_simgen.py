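import math

import numpy as np
import pytest
from scipy import stats

from nanomap.imageproc import HeightImage
from nanomap.mapmatch import ReferenceMap, Site
from nanomap.simgen import (
    Placement,
    SimConfig,
    SimMolecule,
    apply_labels,
    make_ladder_sample,
    render_frame,
    sample_wlc_chain,
)


def arc_length(path):
    return float(np.sum(np.hypot(*np.diff(path, axis=0).T)))


class TestSimConfig:
    def test_defaults_match_instrument_model(self):
        cfg = SimConfig()
        assert cfg.dna_height_nm == 0.3
        assert cfg.label_height_nm == 3.0
        assert cfg.pixel_size_nm == 2.5
        assert cfg.bp_per_nm == 2.94

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(dna_height_nm=-1.0),
            dict(labeling_efficiency=1.5),
            dict(noise_sd_nm=-0.1),
            dict(pixel_size_nm=0.0),
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestWlcChain:
    def test_arc_length_matches_calibration(self, rng):
        # 680 bp / 2.94 bp/nm = 231.3 nm
        cfg = SimConfig()
        path = sample_wlc_chain(680, cfg, rng)
        assert arc_length(path) == pytest.approx(680 / 2.94, rel=1e-3)

    def test_single_bp_two_point_path(self, rng):
        cfg = SimConfig()
        path = sample_wlc_chain(1, cfg, rng)
        assert path.shape == (2, 2)
        assert arc_length(path) == pytest.approx(1 / 2.94, rel=1e-6)

    def test_non_positive_length_rejected(self, rng):
        with pytest.raises(ValueError, match="length_bp"):
            sample_wlc_chain(0, SimConfig(), rng)

    def test_tangent_correlation_decay(self, rng):
        # Monte-Carlo oracle: for the 2D convention the mean cosine of the
        # tangent angle change over separation s is exp(-s / (2 lp)).
        cfg = SimConfig(persistence_length_nm=50.0, pixel_size_nm=2.5)
        sep_nm = 50.0
        step = cfg.pixel_size_nm
        lag = int(round(sep_nm / step))
        vals = []
        for _ in range(1000):
            path = sample_wlc_chain(2000, cfg, rng)
            tang = np.diff(path, axis=0)
            theta = np.arctan2(tang[:, 1], tang[:, 0])
            dtheta = theta[lag:] - theta[:-lag]
            vals.append(np.mean(np.cos(dtheta)))
        vals = np.asarray(vals)
        expected = math.exp(-sep_nm / (2 * cfg.persistence_length_nm))
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean() - expected) < 3 * se + 1e-3

    def test_heading_limit_makes_path_monotone(self, rng):
        cfg = SimConfig(heading_limit_rad=0.9)
        path = sample_wlc_chain(5000, cfg, rng)
        tang = np.diff(path, axis=0)
        theta0 = math.atan2(tang[0, 1], tang[0, 0])
        c, s = math.cos(-theta0), math.sin(-theta0)
        along = tang[:, 0] * c - tang[:, 1] * s
        assert np.all(along > 0)  # strictly advancing -> self-avoiding


class TestApplyLabels:
    def test_full_efficiency_binds_all_perfect_sites(self, rng, tert_map):
        cfg = SimConfig(labeling_efficiency=1.0, off_target_rate=0.0)
        mol = SimMolecule("m", 680, sample_wlc_chain(680, cfg, rng))
        labeled = apply_labels(mol, tert_map, cfg, rng)
        assert [lb.bound for lb in labeled.truth_labels] == [True, True]
        assert all(lb.kind == "perfect" for lb in labeled.truth_labels)

    def test_length_mismatch_rejected(self, rng, tert_map):
        cfg = SimConfig()
        mol = SimMolecule("m", 700, sample_wlc_chain(700, cfg, rng))
        with pytest.raises(ValueError, match="length"):
            apply_labels(mol, tert_map, cfg, rng)

    def test_bound_fraction_matches_binomial_oracle(self, rng):
        # binomial oracle: 5 sites x n molecules at p=0.9
        p, n_sites, n_mol = 0.9, 5, 10_000
        refmap = ReferenceMap("x", 1000, [Site(100 + 150 * i, "perfect") for i in range(n_sites)])
        cfg = SimConfig(labeling_efficiency=p, off_target_rate=0.0)
        path = sample_wlc_chain(1000, cfg, rng)
        bound = 0
        for _ in range(n_mol):
            mol = apply_labels(SimMolecule("m", 1000, path), refmap, cfg, rng)
            bound += sum(lb.bound for lb in mol.truth_labels)
        total = n_sites * n_mol
        se = math.sqrt(p * (1 - p) / total)
        assert abs(bound / total - p) < 3 * se

    def test_off_target_count_matches_poisson_oracle(self, rng):
        rate, n_mol = 0.5, 10_000
        refmap = ReferenceMap("x", 1000, [])
        cfg = SimConfig(off_target_rate=rate)
        path = sample_wlc_chain(1000, cfg, rng)
        counts = []
        for _ in range(n_mol):
            mol = apply_labels(SimMolecule("m", 1000, path), refmap, cfg, rng)
            counts.append(sum(lb.kind == "off_target" for lb in mol.truth_labels))
        se = math.sqrt(rate / n_mol)  # Poisson mean standard error
        assert abs(np.mean(counts) - rate) < 3 * se

    def test_occupancy_chi_square_goodness_of_fit(self, rng):
        # spec invariant: occupancy binomial at alpha=0.001 over 10,000 molecules
        p, n_sites, n_mol = 0.9, 5, 10_000
        refmap = ReferenceMap("x", 1000, [Site(100 + 150 * i, "perfect") for i in range(n_sites)])
        cfg = SimConfig(labeling_efficiency=p, off_target_rate=0.0)
        path = sample_wlc_chain(1000, cfg, rng)
        counts = np.zeros(n_sites + 1)
        for _ in range(n_mol):
            mol = apply_labels(SimMolecule("m", 1000, path), refmap, cfg, rng)
            counts[sum(lb.bound for lb in mol.truth_labels)] += 1
        expected = np.array([stats.binom.pmf(k, n_sites, p) for k in range(n_sites + 1)]) * n_mol
        keep = expected >= 1.0  # merge ultra-rare bins for chi2 validity
        chi2 = np.sum((counts[keep] - expected[keep]) ** 2 / expected[keep])
        chi2 += (counts[~keep].sum() - expected[~keep].sum()) ** 2 / max(expected[~keep].sum(), 1e-9)
        dof = keep.sum()  # conservative
        assert stats.chi2.sf(chi2, dof) > 0.001


class TestRenderFrame:
    def test_empty_frame_statistics(self, rng):
        cfg = SimConfig(noise_sd_nm=0.1, line_offset_sd_nm=0.0)
        img, truth = render_frame([], cfg, rng, frame_size_px=(200, 200))
        assert abs(img.heights.mean()) < 0.01
        assert img.heights.max() < 0.6
        assert truth.table.empty

    def test_label_peak_height_is_3nm(self, rng, quiet_cfg, tert_map):
        cfg = SimConfig(noise_sd_nm=0.0, line_offset_sd_nm=0.0, labeling_efficiency=1.0)
        mol = apply_labels(
            SimMolecule("m", 680, sample_wlc_chain(680, cfg, rng)), tert_map, cfg, rng
        )
        img, _ = render_frame([mol], cfg, rng, frame_size_px=(300, 300))
        assert img.heights.max() == pytest.approx(3.0, abs=1e-6)

    def test_unlabeled_straight_ridge_height(self, rng):
        cfg = SimConfig(noise_sd_nm=0.0, line_offset_sd_nm=0.0)
        path = np.column_stack([np.linspace(0, 150, 150), np.zeros(150)])
        mol = SimMolecule("m", int(150 * cfg.bp_per_nm), path)
        img, _ = render_frame(
            [mol], cfg, rng, placements=[Placement((100.0, 100.0), 0.0)], frame_size_px=(100, 100)
        )
        row = int(round(100 / cfg.pixel_size_nm))
        ridge = img.heights[row, 45:55]
        assert np.allclose(ridge, 0.3, atol=0.05)

    def test_ridge_height_orientation_independent(self, rng):
        # a diagonal molecule must be as tall as an axis-aligned one
        cfg = SimConfig(noise_sd_nm=0.0, line_offset_sd_nm=0.0)
        path = np.column_stack([np.linspace(0, 150, 150), np.zeros(150)])
        mol = SimMolecule("m", int(150 * cfg.bp_per_nm), path)
        img, _ = render_frame(
            [mol], cfg, rng, placements=[Placement((60.0, 60.0), math.pi / 4)], frame_size_px=(100, 100)
        )
        on_path = [
            img.heights[int(round((60 + t / math.sqrt(2)) / 2.5)), int(round((60 + t / math.sqrt(2)) / 2.5))]
            for t in range(20, 130, 5)
        ]
        assert min(on_path) > 0.25

    def test_truth_contour_matches_configured_length(self, rng, quiet_cfg):
        mol = SimMolecule("m", 680, sample_wlc_chain(680, quiet_cfg, rng))
        _, truth = render_frame([mol], quiet_cfg, rng, frame_size_px=(300, 300))
        contour = truth.table["contour_nm"].iloc[0]
        assert contour == pytest.approx(680 / 2.94, rel=1e-3)

    def test_seed_determinism(self, tert_map):
        cfg = SimConfig(noise_sd_nm=0.1, line_offset_sd_nm=0.1, seed=42)
        outs = []
        for _ in range(2):
            rng = cfg.rng()
            mol = apply_labels(
                SimMolecule("m", 680, sample_wlc_chain(680, cfg, rng)), tert_map, cfg, rng
            )
            img, truth = render_frame([mol], cfg, rng, frame_size_px=(300, 300))
            outs.append((img.heights, truth.table))
        np.testing.assert_array_equal(outs[0][0], outs[1][0])
        assert outs[0][1].equals(outs[1][1])

    def test_noise_free_render_idempotent(self, rng, quiet_cfg):
        mol = SimMolecule("m", 680, sample_wlc_chain(680, quiet_cfg, rng))
        r1 = np.random.default_rng(0)
        r2 = np.random.default_rng(0)
        img1, t1 = render_frame([mol], quiet_cfg, r1, frame_size_px=(300, 300))
        img2, t2 = render_frame([mol], quiet_cfg, r2, frame_size_px=(300, 300))
        np.testing.assert_array_equal(img1.heights, img2.heights)

    def test_oversized_molecule_rejected(self, rng, quiet_cfg):
        mol = SimMolecule("m", 12900, sample_wlc_chain(12900, quiet_cfg, rng, heading_limit_rad=0.3))
        from nanomap.simgen import RenderError

        with pytest.raises(RenderError):
            render_frame([mol], quiet_cfg, rng, frame_size_px=(100, 100))

    def test_returns_height_image_with_scale(self, rng, quiet_cfg):
        img, _ = render_frame([], quiet_cfg, rng, frame_size_px=(64, 64))
        assert isinstance(img, HeightImage)
        assert img.pixel_size_nm == quiet_cfg.pixel_size_nm


class TestLadderSample:
    def test_sample_mean_matches_normal_oracle(self, rng):
        tab = make_ladder_sample([140.0], 15_000, 20.0, rng)
        # normal-sampling oracle: se = 20 / sqrt(15000) = 0.163; 4 se = 0.65
        assert abs(tab["measured_bp"].mean() - 140.0) < 0.65

    def test_zero_sd_returns_truth(self, rng):
        tab = make_ladder_sample([140.0, 150.0], 10, 0.0, rng)
        assert (tab["measured_bp"] == tab["species_bp"]).all()

    def test_two_species_mean_difference(self, rng):
        tab = make_ladder_sample([140.0, 142.0], 15_000, 20.0, rng)
        means = tab.groupby("species_bp")["measured_bp"].mean()
        assert abs((means[142.0] - means[140.0]) - 2.0) < 1.0

    def test_empty_lengths_rejected(self, rng):
        with pytest.raises(ValueError):
            make_ladder_sample([], 10, 1.0, rng)
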