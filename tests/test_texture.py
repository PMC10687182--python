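import numpy as np
import pytest

from siribruise.texture import (
    ANGLES,
    HARALICK_NAMES,
    GlcmSpec,
    feature_names,
    feature_vector,
    glcm,
    haralick14,
    quantize_masked,
)

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_force_glcm(quant, valid, angle, levels):
    """Double-loop pair counting, symmetrized and normalized."""
    dr, dc = OFFSETS[angle]
    h, w = quant.shape
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and valid[r, c] and valid[r2, c2]:
                counts[quant[r, c], quant[r2, c2]] += 1
    counts = counts + counts.T
    return counts / counts.sum()


class TestQuantize:
    def test_range_endpoints_map_to_extreme_levels(self):
        img = np.array([[0.0, 0.25], [0.75, 1.0]])
        mask = np.ones((2, 2), bool)
        quant, _ = quantize_masked(img, mask, 4)
        assert quant[0, 0] == 0 and quant[1, 1] == 3

    def test_constant_region_maps_to_zero(self):
        quant, valid = quantize_masked(np.full((3, 3), 2.0), np.ones((3, 3), bool), 8)
        np.testing.assert_array_equal(quant, 0)
        assert valid.all()

    def test_histogram_matches_direct_binning(self, rng):
        img = rng.random((16, 16))
        mask = rng.random((16, 16)) > 0.3
        levels = 8
        quant, valid = quantize_masked(img, mask, levels)
        vals = img[mask]
        lo, hi = vals.min(), vals.max()
        expect = np.minimum(((vals - lo) / (hi - lo) * levels).astype(int), levels - 1)
        got = quant[valid]
        np.testing.assert_array_equal(
            np.bincount(got, minlength=levels), np.bincount(expect, minlength=levels)
        )

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            quantize_masked(np.ones((2, 2)), np.zeros((2, 2), bool), 4)


class TestGlcm:
    def test_two_by_two_hand_example(self):
        img = np.array([[0, 0], [1, 1]])
        valid = np.ones((2, 2), bool)
        p = glcm(img, valid, 0, levels=2)
        np.testing.assert_allclose(p, [[0.5, 0.0], [0.0, 0.5]])

    def test_constant_image_concentrates_at_origin(self):
        p = glcm(np.zeros((4, 4), int), np.ones((4, 4), bool), 90, levels=2)
        assert p[0, 0] == 1.0 and p.sum() == 1.0

    @pytest.mark.parametrize("angle", ANGLES)
    @pytest.mark.parametrize("seed", range(13))
    def test_matches_brute_force_on_random_images(self, angle, seed):
        r = np.random.default_rng(seed)
        quant = r.integers(0, 5, (8, 8))
        valid = r.random((8, 8)) > 0.2
        p = glcm(quant, valid, angle, levels=5)
        np.testing.assert_allclose(p, brute_force_glcm(quant, valid, angle, 5), atol=1e-12)

    def test_symmetry_and_normalization(self, rng):
        quant = rng.integers(0, 6, (12, 12))
        p = glcm(quant, np.ones((12, 12), bool), 45, levels=6)
        assert p.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(p, p.T)

    def test_masked_pairs_excluded(self):
        img = np.array([[0, 1, 0]])
        valid = np.array([[True, False, True]])
        with pytest.raises(ValueError, match="0"):
            # only pairs through the invalid center pixel exist at 0 degrees
            glcm(img, valid, 0, levels=2)


class TestHaralick:
    def test_degenerate_single_entry_matrix(self):
        p = np.zeros((4, 4))
        p[0, 0] = 1.0
        stats = dict(zip(HARALICK_NAMES, haralick14(p)))
        assert stats["asm"] == 1.0
        assert stats["entropy"] == 0.0
        assert stats["contrast"] == 0.0
        assert stats["correlation"] == 0.0  # zero marginal variance fallback
        assert stats["mcc"] == 0.0
        assert np.all(np.isfinite(list(stats.values())))

    def test_two_level_diagonal_matrix_scalar_oracle(self):
        # direct evaluation: p = diag(0.5, 0.5)
        # ASM = 2*0.25; entropy = -2*0.5*log2(0.5) = 1 bit; contrast = 0;
        # marginals uniform -> correlation = (E[ij]-mu^2)/var = (0.5-0.25)/0.25 = 1
        p = np.array([[0.5, 0.0], [0.0, 0.5]])
        stats = dict(zip(HARALICK_NAMES, haralick14(p)))
        assert stats["asm"] == pytest.approx(0.5)
        assert stats["entropy"] == pytest.approx(1.0)
        assert stats["contrast"] == 0.0
        assert stats["correlation"] == pytest.approx(1.0)
        assert stats["idm"] == pytest.approx(1.0)
        assert stats["sum_entropy"] == pytest.approx(1.0)
        assert stats["difference_entropy"] == pytest.approx(0.0)
        assert stats["mcc"] == pytest.approx(1.0)

    def test_three_by_three_matrix_against_defining_sums(self):
        p = np.array([[0.2, 0.05, 0.0], [0.05, 0.3, 0.1], [0.0, 0.1, 0.2]])
        stats = dict(zip(HARALICK_NAMES, haralick14(p)))
        i = np.arange(3)
        ii, jj = np.meshgrid(i, i, indexing="ij")
        assert stats["asm"] == pytest.approx((p**2).sum())
        assert stats["contrast"] == pytest.approx(((ii - jj) ** 2 * p).sum())
        assert stats["idm"] == pytest.approx((p / (1 + (ii - jj) ** 2)).sum())
        nz = p > 0
        assert stats["entropy"] == pytest.approx(-(p[nz] * np.log2(p[nz])).sum())
        px = p.sum(axis=1)
        mu = (i * px).sum()
        var = ((i - mu) ** 2 * px).sum()
        assert stats["variance"] == pytest.approx(var)
        assert stats["correlation"] == pytest.approx(
            ((ii * jj * p).sum() - mu**2) / var
        )

    def test_non_normalized_matrix_rejected(self):
        with pytest.raises(ValueError):
            haralick14(np.ones((3, 3)))


class TestFeatureVector:
    def test_fifty_six_finite_features_with_stable_names(self, rng):
        img = rng.random((32, 32))
        mask = np.ones((32, 32), bool)
        fv = feature_vector(img, mask, GlcmSpec(levels=8))
        assert len(fv.values) == 56
        assert np.all(np.isfinite(fv.values))
        assert fv.feature_names == feature_names()
        assert fv.feature_names[:2] == ("asm_0", "contrast_0")
        assert fv.feature_names[14].endswith("_45")

    def test_deterministic_on_identical_images(self, rng):
        img = rng.random((24, 24))
        mask = np.ones((24, 24), bool)
        a = feature_vector(img, mask, GlcmSpec(levels=8))
        b = feature_vector(img.copy(), mask.copy(), GlcmSpec(levels=8))
        np.testing.assert_array_equal(a.values, b.values)

    def test_rotation_swaps_0_and_90_degree_blocks(self, rng):
        img = rng.random((20, 20))
        mask = rng.random((20, 20)) > 0.1
        spec = GlcmSpec(levels=8)
        base = feature_vector(img, mask, spec).values
        rot = feature_vector(np.rot90(img), np.rot90(mask), spec).values
        # block order per angle: 0, 45, 90, 135; rotating by 90 degrees maps
        # horizontal pairs onto vertical ones
        np.testing.assert_allclose(rot[28:42], base[0:14], atol=1e-9)
        np.testing.assert_allclose(rot[0:14], base[28:42], atol=1e-9)

    def test_constant_masked_region_yields_finite_degenerate_vector(self):
        fv = feature_vector(np.ones((16, 16)), np.ones((16, 16), bool), GlcmSpec(levels=8))
        assert np.all(np.isfinite(fv.values))
        stats = dict(zip(fv.feature_names, fv.values))
        assert stats["asm_0"] == 1.0 and stats["entropy_0"] == 0.0


def test_glcm_matches_skimage_on_full_frame_images(rng):
    """Independent cross-check against skimage's co-occurrence routine."""
    from skimage.feature import graycomatrix

    quant = rng.integers(0, 8, (16, 16)).astype(np.uint8)
    valid = np.ones((16, 16), bool)
    # skimage measures diagonal angles downward in the (row, col) frame, so
    # its pi/4 is our 135-degree (up-left/down-right) direction and vice versa
    for angle, sk_angle in ((0, 0.0), (45, 3 * np.pi / 4), (90, np.pi / 2), (135, np.pi / 4)):
        ours = glcm(quant, valid, angle, levels=8)
        theirs = graycomatrix(
            quant, [1], [sk_angle], levels=8, symmetric=True, normed=True
        )[:, :, 0, 0]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)
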