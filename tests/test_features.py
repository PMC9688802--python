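"""Moment statistics, masked GLCM and the 51-feature descriptor."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sstats
from skimage.feature import graycomatrix as sk_graycomatrix

import spotquant as sq
from spotquant.features import (
    DegenerateGlcm,
    FEATURE_NAMES,
    MOMENT_FEATURE_NAMES,
    TEXTURE_FEATURE_NAMES,
    channel_stats,
    compute_glcm,
    glcm_metrics,
    quantize_gray,
)


from oracles import brute_force_glcm, naive_moments


class TestChannelStats:
    @pytest.mark.parametrize(
        "sample, expected",
        [
            ([4.2] * 5, (4.2, 0.0, 3.0)),  # constant: degenerate rule
            ([0, 0, 1, 1], (0.5, 0.0, 1.0)),  # symmetric two-point
            ([0, 0, 0, 1], (0.25, 1.1547005, 2.3333333)),
        ],
    )
    def test_known_samples(self, sample, expected):
        np.testing.assert_allclose(channel_stats(sample), expected, atol=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            channel_stats([])

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=200))
    def test_matches_naive_oracle(self, sample):
        got = channel_stats(sample)
        want = naive_moments(sample)
        np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-9)

    def test_matches_scipy_conventions(self):
        rng = np.random.default_rng(3)
        v = rng.gamma(2.0, size=500)
        mean, skew, kurt = channel_stats(v)
        assert skew == pytest.approx(sstats.skew(v), rel=1e-12)
        assert kurt == pytest.approx(sstats.kurtosis(v, fisher=False), rel=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=64)
        np.testing.assert_allclose(
            channel_stats(v), channel_stats(rng.permutation(v)), rtol=1e-12
        )


class TestGlcm:
    def test_horizontal_pairs_same_row(self):
        g = compute_glcm(np.array([[0.0, 0.0], [255.0, 255.0]]), Ng=2)
        np.testing.assert_allclose(g.p, [[0.5, 0.0], [0.0, 0.5]])

    def test_horizontal_pairs_across_levels(self):
        g = compute_glcm(np.array([[0.0, 255.0], [0.0, 255.0]]), Ng=2)
        np.testing.assert_allclose(g.p, [[0.0, 0.5], [0.5, 0.0]])

    def test_constant_image_single_cell(self):
        g = compute_glcm(np.full((4, 4), 100.0), Ng=8)
        level = quantize_gray(100.0, 8)
        assert g.p[level, level] == 1.0
        assert g.p.sum() == 1.0

    def test_mask_restricts_pairs(self):
        gray = np.array([[0.0, 255.0, 0.0]])
        mask = np.array([[True, True, False]])
        g = compute_glcm(gray, mask, Ng=2)
        np.testing.assert_allclose(g.p, [[0.0, 0.5], [0.5, 0.0]])

    def test_degenerate_mask_raises(self):
        with pytest.raises(DegenerateGlcm):
            compute_glcm(np.zeros((3, 3)), np.eye(3, dtype=bool), Ng=2)

    @pytest.mark.parametrize("Ng", [2, 4, 8])
    def test_matches_brute_force_oracle(self, Ng):
        rng = np.random.default_rng(20)
        for _ in range(20):
            gray = rng.uniform(0, 255, size=(8, 8))
            mask = rng.random((8, 8)) > 0.2
            if not (mask[:, :-1] & mask[:, 1:]).any():
                continue
            got = compute_glcm(gray, mask, Ng=Ng).p
            want = brute_force_glcm(gray.tolist(), mask.tolist(), Ng, (0, 1))
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_matches_skimage_on_full_frame(self):
        """Independent library cross-check where no mask is involved."""
        rng = np.random.default_rng(21)
        gray = rng.uniform(0, 255, size=(16, 16))
        Ng = 8
        got = compute_glcm(gray, Ng=Ng).p
        levels = quantize_gray(gray, Ng).astype(np.uint8)
        sk = sk_graycomatrix(
            levels, [1], [0], levels=Ng, symmetric=True, normed=True
        )[:, :, 0, 0]
        np.testing.assert_allclose(got, sk, atol=1e-12)


class TestGlcmMetrics:
    def test_perfectly_correlated_diagonal(self):
        g = sq.GlcmMatrix(np.array([[0.5, 0.0], [0.0, 0.5]]), 2, (0, 1), True)
        c, corr, e, h, ent, inten = glcm_metrics(g, [10.0, 20.0])
        assert (c, corr, e, h, ent) == (0.0, 1.0, 0.5, 1.0, 1.0)
        assert inten == 15.0

    def test_anticorrelated_off_diagonal(self):
        g = sq.GlcmMatrix(np.array([[0.0, 0.5], [0.5, 0.0]]), 2, (0, 1), True)
        c, corr, e, h, ent, _ = glcm_metrics(g, [0.0])
        assert (c, corr, e, h, ent) == (1.0, -1.0, 0.5, 0.5, 1.0)

    def test_constant_image_degenerate_rules(self):
        glcm = compute_glcm(np.full((4, 4), 37.0), Ng=8)
        c, corr, e, h, ent, _ = glcm_metrics(glcm, np.full(16, 37.0))
        assert (c, corr, e, h, ent) == (0.0, 1.0, 1.0, 1.0, 0.0)

    def test_metric_ranges_on_random_images(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            gray = rng.uniform(0, 255, size=(12, 12))
            g = compute_glcm(gray, Ng=8)
            c, corr, e, h, ent, _ = glcm_metrics(g, gray.ravel())
            assert 0 < e <= 1 and 0 < h <= 1
            assert -1 <= corr <= 1
            assert 0 <= ent <= 2 * np.log2(8)


class TestExtractFeatures:
    def test_schema_counts(self, segmented_spot):
        pre, mask, _ = segmented_spot
        fv = sq.extract_features(pre, mask)
        assert len(fv.values) == 51
        assert len(MOMENT_FEATURE_NAMES) == 45
        assert len(TEXTURE_FEATURE_NAMES) == 6
        assert fv.names == FEATURE_NAMES

    def test_constant_roi_degenerate_moments(self, clean_scene, fig_model):
        image, truth = sq.simulate_spot(fig_model, clean_scene, 1.0)
        fv = sq.extract_features(image, truth.true_mask)
        d = fv.as_dict()
        for name in MOMENT_FEATURE_NAMES:
            if name.endswith("_skew"):
                assert d[name] == 0.0
            elif name.endswith("_kurt"):
                assert d[name] == 3.0

    def test_deterministic(self, segmented_spot):
        pre, mask, _ = segmented_spot
        a = sq.extract_features(pre, mask).values
        b = sq.extract_features(pre, mask).values
        np.testing.assert_array_equal(a, b)
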