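"""Quantization, mask-restricted summed GLCM, and Haralick features."""

import numpy as np
import pytest

from liverlesion.core import DceSeries, NoPairsError
from liverlesion.texture import (
    HARALICK_FEATURE_NAMES,
    Glcm,
    glcm_summed,
    haralick,
    quantize,
    series_feature_variance,
    texture_features,
)

# ---------------------------------------------------------------------------
# independent oracle: naive textbook formulas over explicit double loops


def haralick_oracle(p):
    """Naive double-loop evaluation of the 13 features (base-2 logs)."""
    n = p.shape[0]
    log2 = lambda x: np.log2(x) if x > 0 else 0.0
    px = [sum(p[i, j] for j in range(n)) for i in range(n)]
    py = [sum(p[i, j] for i in range(n)) for j in range(n)]
    mu_x = sum(i * px[i] for i in range(n))
    mu_y = sum(j * py[j] for j in range(n))
    sx = sum((i - mu_x) ** 2 * px[i] for i in range(n)) ** 0.5
    sy = sum((j - mu_y) ** 2 * py[j] for j in range(n)) ** 0.5
    p_sum = [0.0] * (2 * n - 1)
    p_diff = [0.0] * n
    for i in range(n):
        for j in range(n):
            p_sum[i + j] += p[i, j]
            p_diff[abs(i - j)] += p[i, j]

    asm = sum(p[i, j] ** 2 for i in range(n) for j in range(n))
    contrast = sum(k**2 * p_diff[k] for k in range(n))
    corr = (
        (sum(i * j * p[i, j] for i in range(n) for j in range(n)) - mu_x * mu_y) / (sx * sy)
        if sx > 0 and sy > 0
        else 0.0
    )
    ssv = sum((i - mu_x) ** 2 * p[i, j] for i in range(n) for j in range(n))
    hom = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    s_avg = sum(k * p_sum[k] for k in range(2 * n - 1))
    s_var = sum((k - s_avg) ** 2 * p_sum[k] for k in range(2 * n - 1))
    ent = -sum(p[i, j] * log2(p[i, j]) for i in range(n) for j in range(n))
    s_ent = -sum(q * log2(q) for q in p_sum)
    mu_d = sum(k * p_diff[k] for k in range(n))
    d_var = sum((k - mu_d) ** 2 * p_diff[k] for k in range(n))
    d_ent = -sum(q * log2(q) for q in p_diff)
    hx = -sum(q * log2(q) for q in px)
    hy = -sum(q * log2(q) for q in py)
    hxy1 = -sum(
        p[i, j] * log2(px[i] * py[j]) for i in range(n) for j in range(n)
    )
    hxy2 = -sum(
        px[i] * py[j] * log2(px[i] * py[j]) for i in range(n) for j in range(n)
    )
    imc1 = (ent - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = (max(0.0, 1.0 - 2.0 ** (-2.0 * (hxy2 - ent)))) ** 0.5
    return {
        "asm": asm, "contrast": contrast, "correlation": corr,
        "sum_of_squares_variance": ssv, "homogeneity": hom,
        "sum_average": s_avg, "sum_variance": s_var, "entropy": ent,
        "sum_entropy": s_ent, "difference_variance": d_var,
        "difference_entropy": d_ent, "imc1": imc1, "imc2": imc2,
    }


def random_glcm(rng, n):
    m = rng.uniform(size=(n, n))
    m = m + m.T
    return Glcm(m / m.sum(), n_levels=n)


def brute_force_pairs(labels, mask, n_levels):
    """Enumerate all ordered neighbour pairs in the 8 directions."""
    counts = np.zeros((n_levels, n_levels))
    h, w = labels.shape
    offsets = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            for dy, dx in offsets:
                ny, nx = y + dy, x + dx
                if 0 <= ny < h and 0 <= nx < w and mask[ny, nx]:
                    counts[labels[y, x], labels[ny, nx]] += 1
    return counts / counts.sum()


# ---------------------------------------------------------------------------


class TestQuantize:
    def test_integer_levels_map_to_themselves(self):
        image = np.array([[0.0, 1.0], [2.0, 3.0]])
        mask = np.ones((2, 2), bool)
        assert np.array_equal(quantize(image, mask, 4), [[0, 1], [2, 3]])

    def test_flat_roi_all_level_zero(self):
        labels = quantize(np.full((3, 3), 2.5), np.ones((3, 3), bool), 8)
        assert np.all(labels == 0)

    def test_matches_floor_division_oracle(self, rng):
        image = rng.uniform(-3, 7, size=(10, 10))
        mask = np.ones((10, 10), bool)
        n = 16
        labels = quantize(image, mask, n)
        lo, hi = image.min(), image.max()
        width = (hi - lo) / n
        expected = np.minimum(np.floor((image - lo) / width).astype(int), n - 1)
        assert np.array_equal(labels, expected)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            quantize(np.zeros((3, 3)), np.ones((3, 3), bool), 1)


class TestGlcmSummed:
    def test_two_by_two_matches_brute_force(self):
        labels = np.array([[0, 0], [1, 1]])
        mask = np.ones((2, 2), bool)
        glcm = glcm_summed(labels, mask, n_levels=2)
        expected = brute_force_pairs(labels, mask, 2)
        assert np.allclose(glcm.matrix, expected, atol=1e-12)

    def test_random_image_matches_brute_force(self, rng):
        labels = rng.integers(0, 4, size=(8, 8))
        mask = rng.uniform(size=(8, 8)) > 0.3
        mask[0, 0] = True
        glcm = glcm_summed(labels, mask, n_levels=4)
        assert np.allclose(glcm.matrix, brute_force_pairs(labels, mask, 4), atol=1e-12)

    def test_constant_roi_single_entry(self):
        glcm = glcm_summed(np.zeros((3, 3), int), np.ones((3, 3), bool), n_levels=4)
        assert glcm.matrix[0, 0] == pytest.approx(1.0)
        assert glcm.matrix.sum() == pytest.approx(1.0)

    def test_symmetry_and_normalization(self, rng):
        labels = rng.integers(0, 5, size=(9, 9))
        glcm = glcm_summed(labels, np.ones((9, 9), bool), n_levels=5)
        assert np.allclose(glcm.matrix, glcm.matrix.T)
        assert glcm.matrix.sum() == pytest.approx(1.0, abs=1e-12)

    def test_scattered_pixels_raise_no_pairs(self):
        mask = np.zeros((5, 5), bool)
        mask[0, 0] = mask[4, 4] = mask[0, 4] = True  # no adjacent pairs
        with pytest.raises(NoPairsError):
            glcm_summed(np.zeros((5, 5), int), mask, n_levels=2)


class TestHaralick:
    def test_degenerate_single_level_glcm(self):
        m = np.zeros((4, 4))
        m[0, 0] = 1.0
        feats = haralick(Glcm(m, 4))
        assert feats["asm"] == 1.0
        assert feats["contrast"] == 0.0
        assert feats["entropy"] == 0.0
        assert feats["homogeneity"] == 1.0

    def test_uniform_two_level_glcm_hand_values(self):
        feats = haralick(Glcm(np.full((2, 2), 0.25), 2))
        assert feats["asm"] == pytest.approx(0.25)
        assert feats["entropy"] == pytest.approx(2.0)
        assert feats["contrast"] == pytest.approx(0.5)

    def test_matches_textbook_oracle_on_random_matrices(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 9))
            glcm = random_glcm(rng, n)
            mine = haralick(glcm)
            ref = haralick_oracle(glcm.matrix)
            for name in HARALICK_FEATURE_NAMES:
                assert mine[name] == pytest.approx(ref[name], abs=1e-9), name

    def test_mixing_toward_uniform_monotone_trends(self):
        """ASM and homogeneity fall, entropy rises, along a delta->uniform path."""
        n = 4
        delta = np.zeros((n, n))
        delta[1, 1] = 1.0
        uniform = np.full((n, n), 1.0 / n**2)
        asm, hom, ent = [], [], []
        for lam in np.linspace(0.0, 1.0, 5):
            feats = haralick(Glcm((1 - lam) * delta + lam * uniform, n))
            asm.append(feats["asm"])
            hom.append(feats["homogeneity"])
            ent.append(feats["entropy"])
        assert np.all(np.diff(asm) < 0)
        assert np.all(np.diff(hom) < 0)
        assert np.all(np.diff(ent) > 0)


class TestSeriesFeatureVariance:
    def test_temporally_constant_series_all_zero(self, rng):
        frame = rng.uniform(size=(6, 6))
        series = DceSeries(np.stack([frame] * 4), np.arange(4.0) * 12)
        var = series_feature_variance(series, np.ones((6, 6), bool), n_levels=4)
        assert all(v == pytest.approx(0.0, abs=1e-18) for v in var.values())

    def test_two_frame_population_variance(self, rng):
        a, b = rng.uniform(size=(2, 6, 6))
        series = DceSeries(np.stack([a, b, b]), np.arange(3.0))
        mask = np.ones((6, 6), bool)
        var = series_feature_variance(series, mask, n_levels=4)
        fa = texture_features(a, mask, 4)
        fb = texture_features(b, mask, 4)
        for name in HARALICK_FEATURE_NAMES:
            vals = np.array([fa[name], fb[name], fb[name]])
            assert var[name] == pytest.approx(vals.var(), abs=1e-12)

    def test_frame_order_invariance(self, rng):
        frames = rng.uniform(size=(4, 6, 6))
        mask = np.ones((6, 6), bool)
        fwd = series_feature_variance(DceSeries(frames, np.arange(4.0)), mask, 4)
        rev = series_feature_variance(DceSeries(frames[::-1].copy(), np.arange(4.0)), mask, 4)
        for name in HARALICK_FEATURE_NAMES:
            assert fwd[name] == pytest.approx(rev[name], abs=1e-12)
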