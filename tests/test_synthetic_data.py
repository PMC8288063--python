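"""Stimulus generation, pRF maps, and the voxel-response simulator."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

from visfill import synthetic_data as sd


class TestSceneSet:
    def test_counts_and_shapes(self):
        st = sd.generate_scene_set(24, 6, 64, seed=1)
        assert st.images.shape == (24, 64, 64)
        assert st.images.min() >= 0 and st.images.max() <= 1
        counts = np.bincount(st.categories)
        assert list(counts) == [4] * 6

    def test_non_divisible_count_raises(self):
        with pytest.raises(ValueError):
            sd.generate_scene_set(10, 3, 64)

    def test_single_image_per_category_flagged(self):
        st = sd.generate_scene_set(6, 6, 64, seed=0)
        assert st.n_images == 6
        assert sd.category_contrast(st) is None

    def test_within_category_correlation_exceeds_between(self):
        wins = 0
        for seed in range(20):
            st = sd.generate_scene_set(12, 3, 64, seed=seed)
            within, between = sd.category_contrast(st)
            wins += within > between
        assert wins > 10

    def test_determinism(self):
        a = sd.generate_scene_set(6, 3, 64, seed=9)
        b = sd.generate_scene_set(6, 3, 64, seed=9)
        assert np.array_equal(a.images, b.images)
        c = sd.generate_scene_set(6, 3, 64, seed=10)
        assert not np.array_equal(a.images, c.images)

    def test_png_roundtrip(self, tmp_path):
        st = sd.generate_scene_set(6, 3, 64, seed=2)
        st.save(tmp_path)
        back = sd.StimulusSet.load(tmp_path)
        assert back.ids == st.ids
        assert np.array_equal(back.occluder_mask, st.occluder_mask)
        assert np.abs(back.images - st.images).max() <= 1 / 255 + 1e-9


class TestOccluder:
    def test_forced_quadrant_on_zeros(self):
        out = sd.apply_occluder(np.zeros((4, 4)))
        assert np.array_equal(out[2:, 2:], np.ones((2, 2)))
        assert out.sum() == 4

    def test_idempotent_on_white(self):
        img = np.ones((8, 8))
        assert np.array_equal(sd.apply_occluder(img), img)

    def test_complement_untouched(self, rng):
        img = rng.random((256, 256))
        out = sd.apply_occluder(img)
        mask = np.zeros((256, 256), dtype=bool)
        mask[128:, 128:] = True
        assert np.array_equal(out[~mask], img[~mask])
        assert np.all(out[mask] == 1.0)
        assert mask.sum() == 128 * 128

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            sd.apply_occluder(np.full((4, 4), 2.0))


class TestPRFMap:
    def test_sigma_at_zero_eccentricity_is_intercept(self):
        cfg = sd.PRFConfig()
        prf = sd.plant_prf_map(cfg)
        # the linear model evaluated at the origin
        v1 = prf.lines["V1"]
        assert v1[0] == cfg.v1_intercept
        np.testing.assert_allclose(
            prf.sigma, [prf.lines[r][0] + prf.lines[r][1] * e
                        for r, e in zip(prf.roi, prf.eccentricity)])

    def test_default_v1_pixel_range(self):
        prf = sd.plant_prf_map(sd.PRFConfig(seed=4))
        v1 = prf.sigma_px()[prf.mask("V1")]
        v2 = prf.sigma_px()[prf.mask("V2")]
        assert 3 <= v1.min() < v1.max() <= 16
        assert 3 <= v2.min() < v2.max() <= 21
        assert prf.lines["V2"][1] >= prf.lines["V1"][1]

    def test_linear_refit_recovers_planted_line(self):
        cfg = sd.PRFConfig(n_voxels=100, seed=11)
        prf = sd.plant_prf_map(cfg)
        m = prf.mask("V1")
        slope, intercept = np.polyfit(prf.eccentricity[m], prf.sigma[m], 1)
        assert abs(slope - cfg.v1_slope) < 1e-3
        assert abs(intercept - cfg.v1_intercept) < 1e-3

    def test_nonpositive_intercept_rejected(self):
        with pytest.raises(ValueError):
            sd.PRFConfig(v1_intercept=0.0)


class TestVoxelSelection:
    def test_center_voxel_with_tiny_sigma_retained(self):
        prf = _manual_prf(x=[4.0], y=[-3.0], sigma=[0.01])
        assert sd.select_voxels_by_prf(prf).n_voxels == 1

    def test_border_voxel_always_excluded(self):
        prf = _manual_prf(x=[0.0, 2.0], y=[-3.0, -2.0], sigma=[0.001, 0.1])
        kept = sd.select_voxels_by_prf(prf)
        assert kept.n_voxels == 1 and kept.x[0] == 2.0

    def test_matches_exhaustive_disc_containment(self):
        prf = sd.plant_prf_map(sd.PRFConfig(n_voxels=60, seed=5))
        kept = sd.select_voxels_by_prf(prf)
        kept_keys = set(zip(kept.x, kept.y))
        ang = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        for x, y, s, q in zip(prf.x, prf.y, prf.sigma, prf.quadrant):
            x0, x1, y0, y1 = sd.quadrant_region_deg(q)
            px = x + 2 * s * np.cos(ang)
            py = y + 2 * s * np.sin(ang)
            inside = np.all((px >= x0) & (px <= x1) & (py >= y0) & (py <= y1))
            assert ((x, y) in kept_keys) == bool(inside)

    def test_empty_group_raises_naming_roi(self):
        prf = _manual_prf(x=[4.0], y=[-3.0], sigma=[50.0])
        with pytest.raises(sd.EmptySelectionError, match="V1"):
            sd.select_voxels_by_prf(prf)


def _manual_prf(x, y, sigma, roi=None, quadrant=None):
    n = len(x)
    return sd.PRFMap(np.asarray(x, float), np.asarray(y, float), np.asarray(sigma, float),
                     np.asarray(roi if roi else ["V1"] * n),
                     np.asarray(quadrant if quadrant else ["occluded"] * n),
                     {"V1": (0.2, 0.1), "V2": (0.2, 0.12)}, 256)


from conftest import make_grid_prf as _grid_prf


class TestSimulator:
    def _feats(self, rng, d=8):
        return {"layerA": rng.standard_normal((24, d)),
                "layerB": rng.standard_normal((24, d))}

    def test_default_design_shape(self, rng):
        prf = _grid_prf()
        cfg = sd.StudyConfig(n_subjects=3, geometry_source="layerA", seed=1)
        ds = sd.simulate_voxel_responses(None, self._feats(rng), cfg, prf)
        assert ds.responses.shape == (3, 8, 24, prf.n_voxels)
        assert cfg.presentations == 16
        for q in ("occluded", "nonoccluded"):
            assert ds.ground_truth[q].shape == (24 * 23 // 2,)

    def test_seed_changes_responses_not_ground_truth(self, rng):
        prf = _grid_prf()
        feats = self._feats(rng)
        a = sd.simulate_voxel_responses(None, feats, sd.StudyConfig(
            n_subjects=2, geometry_source="layerA", seed=1), prf)
        b = sd.simulate_voxel_responses(None, feats, sd.StudyConfig(
            n_subjects=2, geometry_source="layerA", seed=2), prf)
        assert not np.array_equal(a.responses, b.responses)
        for q in a.ground_truth:
            np.testing.assert_array_equal(a.ground_truth[q], b.ground_truth[q])

    def test_determinism_bit_identical(self, rng):
        prf = _grid_prf()
        feats = self._feats(rng)
        cfg = sd.StudyConfig(n_subjects=2, geometry_source="layerA", seed=3)
        a = sd.simulate_voxel_responses(None, feats, cfg, prf)
        b = sd.simulate_voxel_responses(None, feats, cfg, prf)
        assert np.array_equal(a.responses, b.responses)

    def test_noiseless_split_half_matches_ground_truth_exactly(self, rng):
        # voxel count per group (16) is a multiple of the mixture dimension
        # (8), and gains are off, so pattern distances are an exact positive
        # multiple of the planted distances
        prf = _grid_prf(16)
        cfg = sd.StudyConfig(n_subjects=1, geometry_source="layerA",
                             noise_sd=0.0, gain_sd=0.0, seed=1)
        ds = sd.simulate_voxel_responses(None, self._feats(rng), cfg, prf)
        half = ds.group("V1", "occluded")[0, :4].mean(axis=0)
        rdm = pdist(half, "sqeuclidean")
        rho = spearmanr(rdm, ds.ground_truth["occluded"]).statistic
        assert rho == pytest.approx(1.0)

    def test_mixture_weights_validated(self, rng):
        with pytest.raises(ValueError):
            sd.StudyConfig(mixing={"layerA": -1.0})
        with pytest.raises(ValueError):
            sd.StudyConfig()  # neither source nor mixing

    def test_unknown_feature_space_raises(self, rng):
        prf = _grid_prf()
        cfg = sd.StudyConfig(n_subjects=1, geometry_source="nope", seed=0)
        with pytest.raises(KeyError):
            sd.simulate_voxel_responses(None, self._feats(rng), cfg, prf)

    def test_condition_count_mismatch_raises(self, rng):
        prf = _grid_prf()
        st = sd.generate_scene_set(6, 3, 64, seed=0)
        cfg = sd.StudyConfig(n_subjects=1, geometry_source="layerA", seed=0)
        with pytest.raises(ValueError):
            sd.simulate_voxel_responses(st, self._feats(rng), cfg, prf)

    def test_reliability_decreases_with_noise(self, rng):
        prf = _grid_prf()
        feats = self._feats(rng)
        grid = [0.5, 1.5, 3.0, 5.0, 8.0]
        means = []
        for ns in grid:
            vals = [sd.split_half_reliability(sd.simulate_voxel_responses(
                None, feats, sd.StudyConfig(n_subjects=2, geometry_source="layerA",
                                            noise_sd=ns, seed=s), prf))
                for s in range(10)]
            means.append(np.mean(vals))
        assert all(b < a for a, b in zip(means, means[1:]))

    def test_hdf5_roundtrip(self, rng, tmp_path):
        prf = _grid_prf()
        cfg = sd.StudyConfig(n_subjects=2, geometry_source="layerA", seed=1)
        ds = sd.simulate_voxel_responses(None, self._feats(rng), cfg, prf)
        ds.to_hdf5(tmp_path / "vox.h5")
        back = sd.VoxelDataset.from_hdf5(tmp_path / "vox.h5")
        np.testing.assert_array_equal(back.responses, ds.responses)
        np.testing.assert_array_equal(back.prf.sigma, ds.prf.sigma)
        for q in ds.ground_truth:
            np.testing.assert_array_equal(back.ground_truth[q], ds.ground_truth[q])
        assert back.config.noise_sd == cfg.noise_sd
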