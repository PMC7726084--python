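"""Worked micro-examples and structural invariants of the feature panel."""

import numpy as np
import pytest

from relomics.features import (
    FEATURE_NAMES,
    build_glcm,
    build_glrlm,
    build_glszm,
    build_ngtdm,
    extract_all,
    glcm_features,
    global_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
    shape_features,
    _runs_for_direction,
)
from relomics.image import Image3D, Mask3D


class TestShape:
    def test_unit_voxel_cube_sphericity(self):
        # V = 1 mm^3, A = 6 mm^2 -> pi^(1/3) 6^(2/3) / 6 ~ 0.806
        mask = Mask3D(np.pad(np.ones((1, 1, 1), bool), 1), 1.0)
        vol, sph = shape_features(mask)
        assert vol == pytest.approx(0.001)
        assert sph == pytest.approx(np.pi ** (1 / 3) * 6 ** (2 / 3) / 6, rel=0.025)

    def test_digital_sphere_near_unity(self):
        g = np.indices((45, 45, 45)) - 22
        ball = (g**2).sum(axis=0) <= 20**2
        _, sph = shape_features(Mask3D(ball, 1.0))
        assert 0.95 <= sph <= 1.0 + 0.01

    def test_sphere_beats_elongated_shape(self):
        g = np.indices((45, 45, 45)) - 22
        ball = (g**2).sum(axis=0) <= 10**2
        _, sph_ball = shape_features(Mask3D(ball, 1.0))
        slab = np.zeros((45, 45, 45), bool)
        slab[5:40, 20:24, 20:24] = True
        _, sph_slab = shape_features(Mask3D(slab, 1.0))
        assert sph_ball > sph_slab

    def test_deterministic(self):
        g = np.indices((15, 15, 15)) - 7
        ball = (g**2).sum(axis=0) <= 5**2
        a = shape_features(Mask3D(ball, 1.3))
        b = shape_features(Mask3D(ball.copy(), 1.3))
        assert a == b


class TestGlobal:
    def test_constant_has_zero_variance_and_undefined_rest(self):
        with pytest.warns(RuntimeWarning):
            out = global_features(np.ones(4))
        assert out["variance"] == 0.0
        assert np.isnan(out["CoV"])

    def test_hand_computed_cov(self):
        # population sd 5, mean 5 -> CoV = 1
        out = global_features(np.array([0.0, 0.0, 10.0, 10.0]))
        assert out["CoV"] == pytest.approx(1.0)
        assert out["variance"] == pytest.approx(25.0)

    def test_symmetric_sample_skewness_small(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=20_000)
        assert abs(global_features(v)["skewness"]) < 0.05


class TestGLCM:
    def test_uniform_roi_single_entry(self, make_roi):
        q = make_roi(np.ones((3, 3, 3), int), ng=1)
        m = build_glcm(q)
        assert m.matrix[0, 0] == pytest.approx(1.0)
        f = glcm_features(m)
        assert f["contrast"] == 0.0
        assert f["energy"] == pytest.approx(1.0)
        assert f["correlation"] == 0.0  # degenerate sigma convention

    def test_slab_pair_counts_by_hand(self, make_roi):
        # 2x2x1 slab levels [[1,2],[1,2]]: 2 same-level pairs, 4 cross pairs
        q = make_roi(np.array([[[1], [2]], [[1], [2]]]), ng=2)
        m = build_glcm(q)
        assert m.meta["n_pairs"] == 6
        assert m.matrix[0, 0] == pytest.approx(2 / 12)
        assert m.matrix[0, 1] == pytest.approx(4 / 12)
        assert m.matrix[1, 0] == pytest.approx(4 / 12)

    def test_single_voxel_raises(self, make_roi):
        levels = np.zeros((3, 3, 3), int)
        levels[1, 1, 1] = 1
        with pytest.raises(ValueError, match="pairs"):
            build_glcm(make_roi(levels, ng=1))


class TestGLRLM:
    def test_uniform_line_runs(self, make_roi):
        q = make_roi(np.ones((1, 1, 4), int), ng=1)
        lv, ln = _runs_for_direction(q.levels, (0, 0, 1))
        assert list(ln) == [4]
        m = build_glrlm(q)
        # axial: one run of 4; other 12 directions: 4 runs of 1 each
        assert m.matrix[0, 3] == 1
        assert m.matrix[0, 0] == 48

    def test_alternating_line_all_short_runs(self, make_roi):
        levels = np.zeros((1, 1, 6), int)
        levels[0, 0, :] = [1, 2, 1, 2, 1, 2]
        lv, ln = _runs_for_direction(levels, (0, 0, 1))
        assert np.all(ln == 1)
        f = glrlm_features(build_glrlm(make_roi(levels, ng=2)))
        assert f["SRE"] == pytest.approx(1.0)

    def test_run_voxel_conservation(self, make_roi):
        rng = np.random.default_rng(0)
        levels = rng.integers(1, 4, size=(4, 4, 4))
        q = make_roi(levels, ng=3)
        m = build_glrlm(q)
        j = np.arange(1, m.matrix.shape[1] + 1)
        assert (m.matrix * j).sum() == q.n_voxels * 13


class TestGLSZM:
    def test_uniform_single_zone(self, make_roi):
        f = glszm_features(build_glszm(make_roi(np.ones((4, 4, 4), int), ng=1)))
        assert f["ZP"] == pytest.approx(1 / 64)
        assert f["ZSN"] == pytest.approx(1.0)

    def test_checkerboard_two_zones(self, make_roi):
        g = np.indices((4, 4, 4)).sum(axis=0) % 2 + 1
        f = glszm_features(build_glszm(make_roi(g, ng=2)))
        # 26-connectivity joins diagonals: 2 zones of 32
        assert f["ZP"] == pytest.approx(2 / 64)
        assert f["ZSN"] == pytest.approx(2.0)

    def test_single_deviant_voxel(self, make_roi):
        levels = np.ones((4, 4, 4), int)
        levels[0, 0, 0] = 2
        f = glszm_features(build_glszm(make_roi(levels, ng=2)))
        assert f["ZSN"] == pytest.approx(1.0)  # (1^2 + 1^2) / 2

    def test_zone_voxel_conservation(self, make_roi):
        rng = np.random.default_rng(1)
        levels = rng.integers(1, 5, size=(5, 5, 5))
        q = make_roi(levels, ng=4)
        m = build_glszm(q)
        j = np.arange(1, m.matrix.shape[1] + 1)
        assert (m.matrix * j).sum() == q.n_voxels

    def test_zp_finer_texture_higher(self, make_roi):
        g = np.indices((4, 4, 4)).sum(axis=0) % 2 + 1
        zp_checker = glszm_features(build_glszm(make_roi(g, ng=2)))["ZP"]
        zp_uniform = glszm_features(build_glszm(make_roi(np.ones((4, 4, 4), int), ng=2)))["ZP"]
        assert zp_checker > zp_uniform


class TestNGTDM:
    def test_uniform_degenerate_conventions(self, make_roi):
        f = ngtdm_features(build_ngtdm(make_roi(np.ones((4, 4, 4), int), ng=2)))
        assert f["coarseness"] == 1.0e6
        assert f["busyness"] == 0.0
        assert f["complexity"] == 0.0
        assert f["strength"] == 0.0

    def test_heterogeneity_raises_busyness(self, make_roi):
        g = np.indices((4, 4, 4)).sum(axis=0) % 2 + 1
        busy = ngtdm_features(build_ngtdm(make_roi(g, ng=2)))["busyness"]
        assert busy > 0.0


class TestExtractAll:
    @pytest.fixture(scope="class")
    def lesion(self):
        rng = np.random.default_rng(4)
        vals = rng.gamma(4.0, 1.0, (14, 14, 14))
        g = np.indices((14, 14, 14)) - 6.5
        # radius small enough that a 2-voxel roll stays inside the grid
        mask = (g**2).sum(axis=0) <= 4.5**2
        return Image3D(vals, 2.0), Mask3D(mask, 2.0)

    def test_complete_named_vector(self, lesion):
        feats = extract_all(*lesion, ng=8, target_mm=2.0)
        assert tuple(feats.keys()) == FEATURE_NAMES
        assert len(feats) == 46
        assert all(np.isfinite(v) for v in feats.values())
        assert 0 < feats["glszm_ZP"] <= 1

    def test_duplicate_inputs_identical(self, lesion):
        img, mask = lesion
        a = extract_all(img, mask, ng=8, target_mm=2.0)
        b = extract_all(
            Image3D(img.values.copy(), img.spacing), Mask3D(mask.values.copy(), mask.spacing),
            ng=8, target_mm=2.0,
        )
        assert a == b

    def test_translation_invariance(self, lesion):
        img, mask = lesion
        a = extract_all(img, mask, ng=8, target_mm=2.0)
        shifted_img = Image3D(np.roll(img.values, 2, axis=0), img.spacing, origin=[50, 0, 0])
        shifted_mask = Mask3D(np.roll(mask.values, 2, axis=0), mask.spacing, origin=[50, 0, 0])
        b = extract_all(shifted_img, shifted_mask, ng=8, target_mm=2.0)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-9), k

    def test_two_voxel_roi_minimal_contract(self):
        vals = np.full((5, 5, 5), 4.0)
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2:4] = True
        feats = extract_all(Image3D(vals, 1.0), Mask3D(mask, 1.0), ng=4, target_mm=1.0)
        assert np.isfinite(feats["volume"])
        assert np.isfinite(feats["sphericity"])
        assert np.isfinite(feats["glcm_energy"])  # one pair exists
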