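import numpy as np
import pytest

from mritexture.glcm import (
    DEFAULT_DIRECTIONS,
    EmptyGlcmError,
    Glcm,
    compute_glcm,
    features_over_directions,
    haralick_features,
)
from mritexture.phantom import generate_textured_field
from mritexture.preprocess import quantize


def glcm_oracle(levels, n_levels, offset, mask=None):
    """Independent double-loop enumeration of symmetrized co-occurrence counts."""
    H, W = levels.shape
    dr, dc = offset
    S = np.zeros((n_levels, n_levels), dtype=int)
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < H and 0 <= c2 < W):
                continue
            if mask is not None and not (mask[r, c] and mask[r2, c2]):
                continue
            S[levels[r, c], levels[r2, c2]] += 1
            S[levels[r2, c2], levels[r, c]] += 1
    return S


class TestComputeGlcm:
    def test_constant_image(self):
        img = np.full((4, 4), 2)
        g = compute_glcm(img, (0, 1), n_levels=4)
        assert g.pair_count == 24  # 12 ordered pairs, symmetrized
        assert g.P[2, 2] == 1.0
        assert g.P.sum() == 1.0

    def test_hand_enumerated_example(self):
        img = np.array([[0, 0, 1, 1], [0, 0, 1, 1], [0, 2, 2, 2], [2, 2, 3, 3]])
        g = compute_glcm(img, (0, 1), n_levels=4)
        S = np.array(
            [[4, 2, 1, 0], [2, 4, 0, 0], [1, 0, 6, 1], [0, 0, 1, 2]], dtype=float
        )
        assert g.pair_count == 24
        assert np.array_equal(g.P, S / 24.0)

    def test_single_pixel_roi_is_empty(self):
        img = np.zeros((5, 5), dtype=int)
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        with pytest.raises(EmptyGlcmError):
            compute_glcm(img, (0, 1), mask=mask, n_levels=4)

    def test_zero_offset_rejected(self):
        with pytest.raises(ValueError):
            compute_glcm(np.zeros((3, 3), int), (0, 0), n_levels=2)

    @pytest.mark.parametrize("offset", DEFAULT_DIRECTIONS)
    def test_matches_enumeration_oracle_with_mask(self, rng, offset):
        levels = rng.integers(0, 4, size=(8, 8))
        mask = rng.uniform(size=(8, 8)) > 0.3
        g = compute_glcm(levels, offset, mask=mask, n_levels=4)
        S = glcm_oracle(levels, 4, offset, mask)
        assert g.pair_count == S.sum()
        assert np.array_equal(g.P, S / S.sum())

    @pytest.mark.parametrize("offset", [(0, 1), (-1, 0)])
    def test_matches_skimage_unmasked(self, rng, offset):
        skimage = pytest.importorskip("skimage.feature")
        levels = rng.integers(0, 8, size=(16, 16))
        g = compute_glcm(levels, offset, n_levels=8)
        # skimage angle convention: (0,1) is angle 0, (-1,0) is angle pi/2
        angle = 0.0 if offset == (0, 1) else np.pi / 2
        ref = skimage.graycomatrix(
            levels.astype(np.uint8), [1], [angle], levels=8, symmetric=True, normed=True
        )[:, :, 0, 0]
        assert np.allclose(g.P, ref, atol=1e-12)

    def test_invariants_on_random_images(self, rng):
        for _ in range(20):
            levels = rng.integers(0, 6, size=(10, 10))
            g = compute_glcm(levels, (-1, 1), n_levels=6)
            assert np.array_equal(g.P, g.P.T)
            assert np.isclose(g.P.sum(), 1.0, atol=1e-12)
            assert (g.P >= 0).all()


class TestHaralickFeatures:
    def test_single_diagonal_cell(self):
        P = np.zeros((4, 4))
        P[1, 1] = 1.0
        f = haralick_features(Glcm(P, 4, (0, 1), 10))
        assert f.energy == 1.0 and f.contrast == 0.0 and f.homogeneity == 1.0
        assert np.isnan(f.correlation)

    def test_perfect_diagonal_has_correlation_plus_one(self):
        f = haralick_features(Glcm(np.diag([0.5, 0.5]), 2, (0, 1), 2))
        assert f == (0.5, 0.0, 1.0, 1.0)

    def test_perfect_antidiagonal_has_correlation_minus_one(self):
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        f = haralick_features(Glcm(P, 2, (0, 1), 2))
        assert f == (0.5, 1.0, 0.5, -1.0)

    def test_matches_direct_formula_on_random_glcms(self, rng):
        i = np.arange(5, dtype=float)
        ii, jj = np.meshgrid(i, i, indexing="ij")
        for _ in range(50):
            C = rng.integers(0, 9, size=(5, 5))
            S = C + C.T
            P = S / S.sum()
            f = haralick_features(Glcm(P, 5, (0, 1), int(S.sum())))
            mu = (ii * P).sum()
            var = ((ii - mu) ** 2 * P).sum()
            assert abs(f.energy - (P**2).sum()) < 1e-12
            assert abs(f.contrast - (P * (ii - jj) ** 2).sum()) < 1e-12
            assert abs(f.homogeneity - (P / (1 + (ii - jj) ** 2)).sum()) < 1e-12
            if var > 1e-12:
                ref = (P * (ii - mu) * (jj - mu)).sum() / var
                assert abs(f.correlation - ref) < 1e-12

    def test_contrast_zero_iff_diagonal(self, rng):
        P = np.diag(rng.dirichlet(np.ones(4)))
        P = (P + P.T) / 2
        f = haralick_features(Glcm(P, 4, (0, 1), 8))
        assert f.contrast == 0.0 and np.isclose(f.homogeneity, 1.0)


class TestDirections:
    def test_constant_image_same_for_both_combine_modes(self):
        img = np.full((6, 6), 3)
        for combine in ("mean_features", "mean_glcm"):
            f, ndir = features_over_directions(img, combine=combine, n_levels=4)
            assert ndir == 4
            assert f.energy == 1.0 and f.contrast == 0.0

    def test_mean_features_is_arithmetic_mean_of_directions(self, rng):
        levels = rng.integers(0, 4, size=(8, 8))
        f, _ = features_over_directions(levels, n_levels=4)
        per_dir = [
            haralick_features(compute_glcm(levels, off, n_levels=4)).contrast
            for off in DEFAULT_DIRECTIONS
        ]
        assert abs(f.contrast - np.mean(per_dir)) < 1e-12

    def test_vertical_stripes_are_anisotropic(self):
        img = np.tile([0, 3], (8, 4))  # columns alternate levels
        c_horiz = haralick_features(compute_glcm(img, (0, 1), n_levels=4)).contrast
        c_vert = haralick_features(compute_glcm(img, (-1, 0), n_levels=4)).contrast
        assert c_horiz > c_vert

    def test_all_directions_empty_raises(self):
        mask = np.zeros((6, 6), bool)
        mask[2, 2] = True
        with pytest.raises(EmptyGlcmError):
            features_over_directions(np.zeros((6, 6), int), mask=mask, n_levels=2)


def test_longer_correlation_length_orders_the_texture():
    """Smoother fields must show higher Homogeneity/Energy and lower
    Contrast — the mechanism behind lesion-versus-background trends."""
    means = {ell: [] for ell in (1.0, 2.0, 4.0)}
    for seed in range(20):
        for ell in means:
            field = generate_textured_field((48, 48), ell, 100.0, 20.0, seed)
            q = quantize(field, 64)
            f, _ = features_over_directions(q)
            means[ell].append([f.energy, f.contrast, f.homogeneity])
    avg = {ell: np.mean(v, axis=0) for ell, v in means.items()}
    for lo, hi in [(1.0, 2.0), (2.0, 4.0)]:
        assert avg[hi][0] > avg[lo][0]  # energy up
        assert avg[hi][1] < avg[lo][1]  # contrast down
        assert avg[hi][2] > avg[lo][2]  # homogeneity up
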