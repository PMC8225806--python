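import numpy as np
import pytest
from skimage.feature import graycomatrix

from oracles import brute_force_glcm
from woundtexture.errors import DegenerateInputError, DegenerateMaskError
from woundtexture.preprocess import MaskedFrame
from woundtexture.texture import (
    DIRECTIONS,
    FEATURE_COLUMNS,
    GLCMatrix,
    average_glcm,
    compute_glcm,
    features_from_frame,
    glcm_features,
    haralick_features,
    normalize_glcm,
    quantize,
)
from woundtexture.thermal_io import ThermalFrame


def _masked(pixels, mask=None):
    pixels = np.asarray(pixels, float)
    if mask is None:
        mask = np.ones_like(pixels, bool)
    return MaskedFrame(pixels=pixels, mask=np.asarray(mask, bool))


def _quantized_from_levels(levels, L):
    levels = np.asarray(levels)
    q = _masked(30.0 + levels.astype(float))
    return quantize(q, n_levels=L, min_pixels=1)


class TestQuantize:
    def test_median_split_of_uniform_range(self):
        q = quantize(_masked([[30.0, 31.0], [32.0, 33.0]]), n_levels=2, min_pixels=1)
        np.testing.assert_array_equal(q.levels, [[0, 0], [1, 1]])
        assert (q.t_min_mask, q.t_max_mask) == (30.0, 33.0)

    def test_shift_invariance(self, rng):
        temps = 28.0 + np.round(rng.uniform(0, 8, (10, 10)) * 64) / 64
        mask = rng.random((10, 10)) > 0.3
        q1 = quantize(_masked(temps, mask), n_levels=16, min_pixels=1)
        q2 = quantize(_masked(temps + 5.0, mask), n_levels=16, min_pixels=1)
        np.testing.assert_array_equal(q1.levels, q2.levels)

    def test_constant_region_degenerate(self):
        q = quantize(_masked(np.full((4, 4), 31.0)), n_levels=8, min_pixels=1)
        assert q.degenerate
        assert (q.levels == 0).all()

    def test_max_maps_to_top_level(self, rng):
        temps = rng.uniform(28, 36, (8, 8))
        q = quantize(_masked(temps), n_levels=16, min_pixels=1)
        assert q.levels[np.unravel_index(temps.argmax(), temps.shape)] == 15
        assert q.levels.min() == 0

    def test_too_few_pixels_rejected(self):
        with pytest.raises(DegenerateMaskError):
            quantize(_masked(np.full((4, 4), 31.0)), n_levels=8, min_pixels=64)


class TestComputeGLCM:
    def test_two_horizontal_same_level_pairs(self):
        q = _quantized_from_levels([[0, 0], [1, 1]], L=2)
        g = compute_glcm(q, distance=1, direction=0)
        np.testing.assert_array_equal(g.P, [[2, 0], [0, 2]])
        assert g.n_pairs == 2

    def test_checkerboard(self):
        q = _quantized_from_levels([[0, 1], [1, 0]], L=2)
        g = compute_glcm(q, distance=1, direction=0)
        np.testing.assert_array_equal(g.P, [[0, 2], [2, 0]])

    def test_unnormalized_counts_sum_to_twice_pairs(self, rng):
        temps = rng.uniform(28, 36, (12, 12))
        mask = rng.random((12, 12)) > 0.4
        q = quantize(_masked(temps, mask), n_levels=8, min_pixels=1)
        for d in DIRECTIONS:
            g = compute_glcm(q, direction=d)
            assert g.P.sum() == 2 * g.n_pairs
            np.testing.assert_array_equal(g.P, g.P.T)

    def test_matches_brute_force_oracle(self, rng):
        """>= 100 random frame/mask/level/direction instances equal the
        explicit double-loop pair count."""
        checked = 0
        for _ in range(30):
            h, w = rng.integers(8, 33, 2)
            L = int(rng.choice([2, 4, 8, 16]))
            temps = rng.uniform(25, 40, (h, w))
            mask = rng.random((h, w)) > 0.3
            if mask.sum() < 2:
                continue
            q = quantize(_masked(temps, mask), n_levels=L, min_pixels=1)
            for d in DIRECTIONS:
                g = compute_glcm(q, direction=d)
                expect = brute_force_glcm(q.levels, mask, L, 1, d)
                np.testing.assert_array_equal(g.P, expect)
                checked += 1
        assert checked >= 100

    def test_excessive_distance_rejected(self):
        q = _quantized_from_levels([[0, 1], [1, 0]], L=2)
        with pytest.raises(DegenerateInputError, match="distance"):
            compute_glcm(q, distance=2, direction=0)

    def test_matches_skimage_on_full_mask(self, rng):
        """On full-frame masks the four directional matrices coincide with
        scikit-image's symmetric co-occurrence matrices."""
        img = rng.integers(0, 8, (16, 20)).astype(np.uint8)
        q = _quantized_from_levels(img, L=8)
        ours = [compute_glcm(q, direction=d).P for d in DIRECTIONS]
        ref = graycomatrix(
            img, [1], [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4], levels=8,
            symmetric=True,
        )
        theirs = [ref[:, :, 0, k] for k in range(4)]
        for mine in ours:
            assert any(np.array_equal(mine, t) for t in theirs)


class TestNormalizeAndAverage:
    def test_normalization_examples(self):
        g = GLCMatrix(np.array([[2.0, 0], [0, 2.0]]), 0, 1, False, 2)
        np.testing.assert_allclose(normalize_glcm(g).P, [[0.5, 0], [0, 0.5]])
        g = GLCMatrix(np.array([[0, 2.0], [2.0, 0]]), 0, 1, False, 2)
        np.testing.assert_allclose(normalize_glcm(g).P, [[0, 0.5], [0.5, 0]])

    def test_normalized_sums_to_one(self, rng):
        temps = rng.uniform(28, 36, (10, 10))
        q = quantize(_masked(temps), n_levels=8, min_pixels=1)
        for d in DIRECTIONS:
            g = normalize_glcm(compute_glcm(q, direction=d))
            assert abs(g.P.sum() - 1.0) < 1e-12

    def test_zero_pairs_rejected(self):
        """A one-row mask has no vertical pairs."""
        mask = np.zeros((4, 4), bool)
        mask[1] = True
        temps = 30.0 + np.arange(16.0).reshape(4, 4)
        q = quantize(_masked(temps, mask), n_levels=4, min_pixels=1)
        with pytest.raises(DegenerateInputError, match="pairs"):
            normalize_glcm(compute_glcm(q, direction=90))


DIAG = np.array([[0.5, 0.0], [0.0, 0.5]])
ANTI = np.array([[0.0, 0.5], [0.5, 0.0]])
SINGLE = np.array([[1.0]])


class TestFeatureValues:
    @pytest.mark.parametrize(
        "P, expected",
        [
            (
                DIAG,
                dict(asm=0.5, contrast=0.0, idm=1.0, entropy=1.0,
                     correlation=1.0, sum_average=1.0, cluster_shade=0.0),
            ),
            (
                ANTI,
                dict(asm=0.5, contrast=1.0, correlation=-1.0, sum_average=1.0),
            ),
            (
                SINGLE,
                dict(asm=1.0, entropy=0.0, contrast=0.0, idm=1.0, correlation=0.0),
            ),
        ],
    )
    def test_closed_form_matrices(self, P, expected):
        fv = glcm_features(P)
        for name, value in expected.items():
            assert getattr(fv, name) == pytest.approx(value, abs=1e-12), name

    def test_direct_summation_oracle(self, rng):
        """Features of a random normalized matrix match naive scalar loops."""
        L = 5
        M = rng.random((L, L))
        M = M + M.T
        P = M / M.sum()
        fv = glcm_features(P)
        asm = sum(P[i, j] ** 2 for i in range(L) for j in range(L))
        contrast = sum((i - j) ** 2 * P[i, j] for i in range(L) for j in range(L))
        ent = -sum(
            P[i, j] * np.log2(P[i, j]) for i in range(L) for j in range(L) if P[i, j] > 0
        )
        mu = sum(i * P[i, j] for i in range(L) for j in range(L))
        var = sum((i - mu) ** 2 * P[i, j] for i in range(L) for j in range(L))
        corr = (
            sum(i * j * P[i, j] for i in range(L) for j in range(L)) - mu * mu
        ) / var
        shade = sum(
            (i + j - 2 * mu) ** 3 * P[i, j] for i in range(L) for j in range(L)
        )
        assert fv.asm == pytest.approx(asm, rel=1e-12)
        assert fv.contrast == pytest.approx(contrast, rel=1e-12)
        assert fv.entropy == pytest.approx(ent, rel=1e-12)
        assert fv.correlation == pytest.approx(corr, rel=1e-12)
        assert fv.sum_of_squares_variance == pytest.approx(var, rel=1e-12)
        assert fv.cluster_shade == pytest.approx(shade, rel=1e-9)

    def test_feature_vector_has_twelve_named_slots(self):
        fv = glcm_features(DIAG)
        assert len(fv.as_array()) == 12
        assert len(FEATURE_COLUMNS) == 12
        assert FEATURE_COLUMNS[0] == "a_asm"
        assert FEATURE_COLUMNS[-1] == "l_cluster_prominence"

    def test_contrast_equals_inertia_everywhere(self, rng):
        for _ in range(10):
            M = rng.random((6, 6))
            M = M + M.T
            fv = glcm_features(M / M.sum())
            assert fv.inertia == fv.contrast

    def test_asm_entropy_tradeoff(self, rng):
        """asm attains 1 exactly when entropy is 0 (single-cell mass)."""
        fv = glcm_features(SINGLE)
        assert fv.asm == 1.0 and fv.entropy == 0.0
        for _ in range(10):
            M = rng.random((4, 4)) + 0.01
            M = M + M.T
            fv = glcm_features(M / M.sum())
            assert fv.asm < 1.0 and fv.entropy > 0.0

    def test_non_normalized_input_rejected(self):
        with pytest.raises(DegenerateInputError, match="normalized"):
            glcm_features(np.array([[2.0, 0], [0, 2.0]]))


def _frame_and_mask(rng, h=24, w=30):
    temps = rng.uniform(26, 38, (h, w))
    mask = np.zeros((h, w), bool)
    mask[4 : h - 4, 5 : w - 5] = True
    mask &= rng.random((h, w)) > 0.2
    return ThermalFrame(pixels=temps), mask


class TestInvariances:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rotation_invariance_exact(self, seed):
        """Direction averaging absorbs the 0<->90 / 45<->135 swap exactly."""
        rng = np.random.default_rng(seed)
        frame, mask = _frame_and_mask(rng)
        fv = features_from_frame(frame, mask, n_levels=8, min_pixels=1)
        rot = ThermalFrame(pixels=np.rot90(frame.pixels).copy())
        fv_rot = features_from_frame(
            rot, np.rot90(mask).copy(), n_levels=8, min_pixels=1
        )
        np.testing.assert_array_equal(fv.as_array(), fv_rot.as_array())

    @pytest.mark.parametrize("seed", [3, 4])
    def test_temperature_affine_invariance(self, seed):
        """T -> aT + b (a > 0) leaves the whole feature vector unchanged."""
        rng = np.random.default_rng(seed)
        h, w = 20, 25
        temps = 28.0 + np.round(rng.uniform(0, 8, (h, w)) * 64) / 64
        mask = rng.random((h, w)) > 0.25
        frame = ThermalFrame(pixels=temps)
        scaled = ThermalFrame(pixels=temps * 2.0 + 4.0)
        fv1 = features_from_frame(frame, mask, n_levels=16, min_pixels=1)
        fv2 = features_from_frame(scaled, mask, n_levels=16, min_pixels=1)
        np.testing.assert_array_equal(fv1.as_array(), fv2.as_array())

    def test_degenerate_constant_region(self):
        frame = ThermalFrame(pixels=np.full((10, 10), 31.0))
        fv = features_from_frame(frame, np.ones((10, 10), bool), min_pixels=1)
        assert fv.asm == 1.0 and fv.entropy == 0.0 and fv.correlation == 0.0

    def test_average_requires_all_four_directions(self, rng):
        temps = rng.uniform(28, 36, (10, 10))
        q = quantize(_masked(temps), n_levels=4, min_pixels=1)
        gs = [normalize_glcm(compute_glcm(q, direction=d)) for d in (0, 45, 90)]
        with pytest.raises(DegenerateInputError):
            average_glcm(gs)
        full = gs + [normalize_glcm(compute_glcm(q, direction=135))]
        fv = haralick_features(full)
        assert np.isfinite(fv.as_array()).all()
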