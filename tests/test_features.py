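"""HSI conversion, GLCM texture features and normalization."""

import math

import numpy as np
import pytest

from tomatoseg.features import (
    DEFAULT_OFFSETS,
    FEATURE_NAMES,
    FeatureConfig,
    NormalizationStats,
    apply_normalization,
    block_feature_vector,
    fit_normalization,
    glcm,
    image_feature_table,
    quantize_grey,
    rgb_to_hsi,
    texture_features,
)
from tomatoseg.imaging import tile_blocks


class TestHsi:
    def test_achromatic_pixel(self):
        h, s, i = rgb_to_hsi((100, 100, 100))
        assert (h, s, i) == (0.0, 0.0, 100.0)

    def test_pure_red(self):
        h, s, i = rgb_to_hsi((255, 0, 0))
        assert h == pytest.approx(0.0)
        assert s == pytest.approx(1.0)
        assert i == pytest.approx(85.0)

    def test_pure_blue_takes_reflected_branch(self):
        h, s, i = rgb_to_hsi((0, 0, 255))
        assert h == pytest.approx(4 * math.pi / 3)

    def test_black_pixel_conventions(self):
        h, s, i = rgb_to_hsi((0, 0, 0))
        assert (h, s, i) == (0.0, 0.0, 0.0)

    def test_hue_range(self, rng):
        for _ in range(200):
            h, s, _ = rgb_to_hsi(tuple(rng.uniform(0, 255, 3)))
            assert 0.0 <= h < 2 * math.pi
            assert 0.0 <= s <= 1.0


def _glcm_brute_force(levels, k, offsets):
    """Double-loop co-occurrence counting (independent oracle)."""
    h, w = levels.shape
    mat = np.zeros((k, k))
    for dr, dc in offsets:
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    mat[levels[r, c], levels[r2, c2]] += 1
                    mat[levels[r2, c2], levels[r, c]] += 1
    total = mat.sum()
    return mat / total if total else mat


class TestGlcm:
    def test_constant_block_all_mass_on_diagonal_cell(self):
        levels = np.full((9, 9), 5)
        G = glcm(levels, 16)
        assert G[5, 5] == pytest.approx(1.0)
        assert G.sum() == pytest.approx(1.0)

    def test_two_by_two_worked_example(self):
        levels = np.array([[0, 1], [0, 1]])
        G = glcm(levels, 2, offsets=((0, 1),))
        assert G[0, 1] == pytest.approx(0.5)
        assert G[1, 0] == pytest.approx(0.5)
        assert G[0, 0] == 0.0 and G[1, 1] == 0.0

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(20):
            levels = rng.integers(0, 16, (9, 9))
            G = glcm(levels, 16, DEFAULT_OFFSETS)
            oracle = _glcm_brute_force(levels, 16, DEFAULT_OFFSETS)
            assert np.abs(G - oracle).max() < 1e-12

    def test_sums_to_one_and_symmetric(self, rng):
        for _ in range(10):
            levels = rng.integers(0, 8, (7, 5))
            G = glcm(levels, 8)
            assert G.sum() == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(G, G.T)

    def test_single_pixel_block_degenerates_gracefully(self):
        G = glcm(np.array([[3]]), 16)
        assert G[3, 3] == 1.0
        assert G.sum() == 1.0

    def test_unquantized_input_rejected(self):
        with pytest.raises(ValueError):
            glcm(np.array([[0, 99]]), 16)


def _texture_brute_force(G, log_base=10.0):
    """Direct double-sum evaluation with 1-based indices (oracle)."""
    k = G.shape[0]
    et = en = im = ls = 0.0
    ui = uj = 0.0
    for i in range(1, k + 1):
        for j in range(1, k + 1):
            g = G[i - 1, j - 1]
            if g > 0:
                et -= g * math.log(g, log_base)
            en += g * g
            im += (i - j) ** 2 * g
            ls += g / (1 + (i - j) ** 2)
            ui += i * g
            uj += j * g
    si = sj = cij = 0.0
    for i in range(1, k + 1):
        for j in range(1, k + 1):
            g = G[i - 1, j - 1]
            si += g * (i - ui) ** 2
            sj += g * (j - uj) ** 2
            cij += i * j * g
    si, sj = math.sqrt(si), math.sqrt(sj)
    cr = 0.0 if si * sj == 0 else (cij - ui * uj) / (si * sj)
    return et, en, cr, im, ls


class TestTextureFeatures:
    def test_constant_block_limits(self):
        G = np.zeros((16, 16))
        G[4, 4] = 1.0
        et, en, cr, im, ls = texture_features(G)
        assert et == 0.0
        assert en == 1.0
        assert cr == 0.0  # convention for vanishing marginal sd
        assert im == 0.0
        assert ls == 1.0

    def test_uniform_two_by_two_worked_example(self):
        G = np.full((2, 2), 0.25)
        et, en, cr, im, ls = texture_features(G)
        assert en == pytest.approx(0.25)
        assert et == pytest.approx(math.log10(4))
        assert im == pytest.approx(0.5)
        assert ls == pytest.approx(0.75)

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(20):
            raw = rng.random((6, 6))
            G = raw + raw.T  # symmetric like a real GLCM
            G /= G.sum()
            got = texture_features(G)
            expected = _texture_brute_force(G)
            np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_feature_ranges_on_random_glcms(self, rng):
        for _ in range(30):
            levels = rng.integers(0, 16, (9, 9))
            et, en, cr, im, ls = texture_features(glcm(levels, 16))
            assert et >= 0.0
            assert 0.0 < en <= 1.0
            assert -1.0 - 1e-12 <= cr <= 1.0 + 1e-12
            assert im >= 0.0
            assert 0.0 < ls <= 1.0

    def test_energy_one_iff_single_cell_and_max_entropy_uniform(self):
        k = 4
        uniform = np.full((k, k), 1.0 / k**2)
        et_u, en_u, *_ = texture_features(uniform)
        assert et_u == pytest.approx(math.log10(k**2))
        assert en_u < 1.0
        single = np.zeros((k, k))
        single[1, 1] = 1.0
        _, en_s, *_ = texture_features(single)
        assert en_s == 1.0


class TestBlockFeatures:
    def test_constant_red_block(self):
        img = np.zeros((9, 9, 3), np.uint8)
        img[:] = (200, 30, 30)
        (block,) = tile_blocks(img)
        v = block_feature_vector(img, block)
        names = dict(zip(FEATURE_NAMES, v))
        assert names["R"] == 200 and names["G"] == 30 and names["B"] == 30
        assert names["Et"] == 0.0 and names["En"] == 1.0
        assert names["Im"] == 0.0 and names["Ls"] == 1.0 and names["Cr"] == 0.0

    def test_red_mean_is_linear(self, rng):
        img = np.zeros((9, 9, 3), np.uint8)
        img[:, :, 0] = rng.integers(0, 100, (9, 9))
        (block,) = tile_blocks(img)
        r1 = block_feature_vector(img, block)[0]
        img2 = img.copy()
        img2[:, :, 0] = img[:, :, 0] * 2  # stays below 255, no clipping
        r2 = block_feature_vector(img2, block)[0]
        assert r2 == pytest.approx(2 * r1)

    def test_matches_per_pixel_brute_force_oracle(self, rng):
        from tomatoseg.features import rgb_to_hsi as hsi

        cfg = FeatureConfig()
        for _ in range(10):
            img = rng.integers(0, 256, (9, 9, 3), dtype=np.uint8)
            (block,) = tile_blocks(img)
            got = block_feature_vector(img, block, cfg)
            means = [float(img[:, :, ch].mean()) for ch in range(3)]
            h, s, i = hsi(tuple(means))
            levels = quantize_grey(img[:, :, 0], cfg.grey_levels)
            G = _glcm_brute_force(levels, cfg.grey_levels, cfg.offsets)
            tex = _texture_brute_force(G, cfg.entropy_log_base)
            expected = np.array([*means, h / (2 * math.pi), s, i, *tex])
            np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_texture_invariant_to_grey_shift_with_shifted_bounds(self, rng):
        block = rng.integers(0, 100, (9, 9)).astype(float)
        shift = 60.0
        lv1 = quantize_grey(block, 16, 0, 100)
        lv2 = quantize_grey(block + shift, 16, shift, 100 + shift)
        np.testing.assert_array_equal(lv1, lv2)
        np.testing.assert_allclose(
            texture_features(glcm(lv1, 16)), texture_features(glcm(lv2, 16))
        )

    def test_image_table_has_one_row_per_block(self, rng):
        img = rng.integers(0, 256, (20, 28, 3), dtype=np.uint8)
        table = image_feature_table(img)
        assert len(table) == len(tile_blocks(img))
        assert list(table.columns[2:]) == list(FEATURE_NAMES)


class TestNormalization:
    def test_min_maps_to_zero_and_max_to_one(self, rng):
        X = rng.random((50, 11)) * 40 - 10
        stats = fit_normalization(X)
        Z = apply_normalization(X, stats)
        assert Z.min() >= 0.0 and Z.max() <= 1.0
        np.testing.assert_allclose(Z.min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.max(axis=0), 1.0, atol=1e-12)

    def test_out_of_range_values_are_clipped(self):
        X = np.array([[0.0] * 11, [10.0] * 11])
        stats = fit_normalization(X)
        z = apply_normalization(np.array([[-5.0] * 11, [20.0] * 11]), stats)
        assert (z[0] == 0.0).all() and (z[1] == 1.0).all()

    def test_degenerate_feature_flagged_and_maps_to_zero(self):
        X = np.ones((5, 11))
        X[:, 1:] = np.random.default_rng(0).random((5, 10))
        stats = fit_normalization(X)
        assert stats.degenerate[0]
        z = apply_normalization(X, stats)
        assert (z[:, 0] == 0.0).all()

    def test_single_vector_rejected(self):
        with pytest.raises(ValueError):
            fit_normalization(np.ones((1, 11)))

    def test_stats_round_trip_through_dict(self, rng):
        stats = fit_normalization(rng.random((10, 11)))
        back = NormalizationStats.from_dict(stats.to_dict())
        np.testing.assert_array_equal(stats.minima, back.minima)
        np.testing.assert_array_equal(stats.maxima, back.maxima)
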