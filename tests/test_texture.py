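"""Texture matrices vs. brute-force enumeration, and feature conventions."""

import numpy as np
import pytest

import oracles
from crferad.texture import (
    TEXTURE_FEATURE_NAMES,
    gldm_matrix,
    glcm_matrix,
    glrlm_matrix,
    glszm_matrix,
    glszm_features,
    ngtdm_matrix,
    quantize,
    texture_features,
    texture_matrices,
)


def pad_to(m, shape):
    out = np.zeros(shape)
    out[: m.shape[0], : m.shape[1]] = m
    return out


class TestQuantize:
    def test_levels_span_one_to_n(self, rng):
        img = rng.normal(size=(10, 10))
        mask = np.ones((10, 10), bool)
        q = quantize(img, mask, 4)
        assert q.min() == 1 and q.max() == 4

    def test_constant_region_single_level(self):
        q = quantize(np.ones((5, 5)), np.ones((5, 5), bool), 8)
        assert set(np.unique(q)) == {1}

    def test_outside_mask_zero(self, rng):
        mask = np.zeros((6, 6), bool)
        mask[2:4, 2:4] = True
        q = quantize(rng.normal(size=(6, 6)), mask, 4)
        assert (q[~mask] == 0).all()


class TestMatrixOracles:
    def test_two_by_two_handworked(self):
        img = np.array([[1.0, 1.0], [2.0, 2.0]])
        mask = np.ones((2, 2), bool)
        q = quantize(img, mask, 2)
        # horizontal direction: runs (1,2) and (2,2)
        rl = glrlm_matrix(q, mask, 2, directions=((0, 1),))
        assert rl[0, 1] == 1 and rl[1, 1] == 1 and rl.sum() == 2
        # horizontal co-occurrence before symmetrization: one (1,1) pair
        cc = glcm_matrix(q, mask, 2, directions=((0, 1),))
        # symmetrized counts: (1,1) appears once in each order
        assert cc[0, 0] == 2 and cc[1, 1] == 2 and cc[0, 1] == 0

    def test_constant_region_degenerate_structures(self):
        img = np.ones((5, 5))
        mask = np.ones((5, 5), bool)
        mats = texture_matrices(img, mask, 8)
        # single 8-connected zone of size 25
        assert mats.glszm[0, 24] == 1 and mats.glszm.sum() == 1
        assert mats.ngtdm_s.sum() == 0.0

    @pytest.mark.parametrize("trial", range(25))
    def test_all_families_match_bruteforce(self, trial):
        rng = np.random.default_rng(1000 + trial)
        h, w = rng.integers(3, 9, size=2)
        n_levels = int(rng.integers(2, 5))
        img = rng.normal(size=(h, w))
        mask = rng.random((h, w)) > 0.2
        if mask.sum() < 2:
            mask[0, 0] = mask[1, 1] = True
        q = quantize(img, mask, n_levels)

        glcm = glcm_matrix(q, mask, n_levels)
        assert np.allclose(glcm, oracles.glcm_bruteforce(q, mask, n_levels))

        rl = glrlm_matrix(q, mask, n_levels)
        rl_o = oracles.glrlm_bruteforce(q, mask, n_levels)
        shape = (n_levels, max(rl.shape[1], rl_o.shape[1]))
        assert np.allclose(pad_to(rl, shape), pad_to(rl_o, shape))

        sz = glszm_matrix(q, mask, n_levels)
        sz_o = oracles.glszm_bruteforce(q, mask, n_levels)
        shape = (n_levels, max(sz.shape[1], sz_o.shape[1]))
        assert np.allclose(pad_to(sz, shape), pad_to(sz_o, shape))

        dm = gldm_matrix(q, mask, n_levels)
        dm_o = oracles.gldm_bruteforce(q, mask, n_levels)
        shape = (n_levels, max(dm.shape[1], dm_o.shape[1]))
        assert np.allclose(pad_to(dm, shape), pad_to(dm_o, shape))

        s, n = ngtdm_matrix(q, mask, n_levels)
        s_o, n_o = oracles.ngtdm_bruteforce(q, mask, n_levels)
        assert np.allclose(s, s_o) and np.allclose(n, n_o)


class TestFeatureConventions:
    def test_family_cardinalities(self):
        assert len(TEXTURE_FEATURE_NAMES["glcm"]) == 24
        assert len(TEXTURE_FEATURE_NAMES["glrlm"]) == 16
        assert len(TEXTURE_FEATURE_NAMES["glszm"]) == 16
        assert len(TEXTURE_FEATURE_NAMES["gldm"]) == 14
        assert len(TEXTURE_FEATURE_NAMES["ngtdm"]) == 5

    def test_single_zone_large_area_emphasis(self):
        counts = np.zeros((4, 25))
        counts[2, 24] = 1  # one zone of size 25
        feats = glszm_features(counts, n_pixels=25)
        assert feats["LargeAreaEmphasis"] == 25**2
        assert feats["SmallAreaEmphasis"] == pytest.approx(1 / 25**2)

    def test_all_features_finite_on_random_fields(self):
        for trial in range(30):
            rng = np.random.default_rng(trial)
            img = rng.normal(size=(12, 12))
            mask = rng.random((12, 12)) > 0.3
            mask[5, 5] = True
            mats = texture_matrices(img, mask, 4)
            feats = texture_features(mats, int(mask.sum()))
            for family, d in feats.items():
                for name, v in d.items():
                    assert np.isfinite(v), f"{family}/{name}"

    def test_degenerate_single_level_defined(self):
        mats = texture_matrices(np.ones((6, 6)), np.ones((6, 6), bool), 4)
        feats = texture_features(mats, 36)
        assert feats["glcm"]["Correlation"] == 0.0
        assert feats["glcm"]["JointEntropy"] == 0.0
        assert all(np.isfinite(v) for d in feats.values() for v in d.values())

    def test_rotation_invariance_of_angle_averaged_glcm(self, rng):
        img = rng.normal(size=(16, 16))
        mask = np.ones((16, 16), bool)
        q = quantize(img, mask, 6)
        a = glcm_matrix(q, mask, 6)
        q90 = np.rot90(q).copy()
        b = glcm_matrix(q90, np.ones((16, 16), bool), 6)
        assert np.allclose(a, b, atol=1e-9)

    def test_monotone_contrast_invariance(self, rng):
        """Strictly increasing intensity maps preserving bin assignment
        leave all quantized-texture features unchanged."""
        img = rng.random((10, 10))
        mask = np.ones((10, 10), bool)
        mats1 = texture_matrices(img, mask, 4)
        q = quantize(img, mask, 4)
        mats2 = texture_matrices(q.astype(float), mask, 4)  # bin index image
        f1 = texture_features(mats1, 100)
        f2 = texture_features(mats2, 100)
        for family in f1:
            for name in f1[family]:
                assert f1[family][name] == pytest.approx(f2[family][name], rel=1e-9)
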