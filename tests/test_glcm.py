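import numpy as np
import pytest

from nmfseg.errors import EmptyMaskError, NoPairsError
from nmfseg.glcm import (
    FEATURE_NAMES,
    GLCMatrix,
    QuantizedSlice,
    _features_batch,
    co_occurrence_counts,
    compute_glcm,
    feature_maps,
    haralick_features,
    marginals,
    quantize,
)

from .oracles import brute_force_counts, random_symmetric_glcm, reference_features


class TestQuantize:
    def test_linear_rescale(self):
        data = np.array([[0.0, 100.0, 200.0]])
        mask = np.ones_like(data, dtype=bool)
        q = quantize(data, mask, 3)
        assert q.data.tolist() == [[0, 1, 2]]

    def test_constant_slice_maps_to_zero(self):
        data = np.full((4, 4), 7.0)
        q = quantize(data, np.ones((4, 4), bool), 8)
        assert (q.data == 0).all()

    def test_identity_when_already_full_range(self):
        data = np.arange(16.0).reshape(4, 4) % 4
        q = quantize(data, np.ones((4, 4), bool), 4)
        assert np.array_equal(q.data, data.astype(int))

    def test_unmasked_pixels_excluded_and_zeroed(self):
        data = np.array([[1000.0, 10.0], [20.0, 30.0]])
        mask = np.array([[False, True], [True, True]])
        q = quantize(data, mask, 3)
        assert q.data[0, 0] == 0
        assert q.data[1, 1] == 2  # max over the mask is 30, not 1000

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            quantize(np.zeros((3, 3)), np.zeros((3, 3), bool), 4)


class TestComputeGLCM:
    def test_hand_case_horizontal(self):
        q = QuantizedSlice(np.array([[0, 0], [0, 1]]), levels=2)
        G = compute_glcm(q, d=1, directions=(0,))
        expected = np.array([[0.5, 0.25], [0.25, 0.0]])
        np.testing.assert_allclose(G.G, expected)

    def test_constant_window_point_mass(self):
        q = QuantizedSlice(np.full((5, 5), 3), levels=8)
        G = compute_glcm(q)
        expected = np.zeros((8, 8))
        expected[3, 3] = 1.0
        np.testing.assert_allclose(G.G, expected)

    def test_symmetric_and_normalized(self, rng):
        for _ in range(20):
            q = QuantizedSlice(rng.integers(0, 6, size=(7, 9)), levels=6)
            G = compute_glcm(q)
            np.testing.assert_allclose(G.G, G.G.T, atol=1e-15)
            assert G.G.sum() == pytest.approx(1.0, abs=1e-12)
            assert G.G.min() >= 0

    def test_counts_match_brute_force(self, rng):
        for _ in range(50):
            h, w = rng.integers(2, 9, size=2)
            N = int(rng.integers(2, 9))
            data = rng.integers(0, N, size=(h, w))
            mask = rng.random((h, w)) > 0.3
            q = QuantizedSlice(data, levels=N)
            for phi in (0, 45, 90, 135):
                got = co_occurrence_counts(q, 1, phi, mask=mask)
                want = brute_force_counts(data, N, 1, phi, mask=mask)
                np.testing.assert_array_equal(got, want)

    def test_rotation_invariance_of_direction_average(self, rng):
        q = QuantizedSlice(rng.integers(0, 5, size=(8, 8)), levels=5)
        q_rot = QuantizedSlice(np.rot90(q.data).copy(), levels=5)
        np.testing.assert_allclose(
            compute_glcm(q).G, compute_glcm(q_rot).G, atol=1e-14
        )

    def test_no_pairs_raises(self):
        q = QuantizedSlice(np.array([[1]]), levels=2)
        with pytest.raises(NoPairsError):
            compute_glcm(q, d=1)


class TestHaralickFeatures:
    def test_point_mass_closed_forms(self):
        G = np.zeros((6, 6))
        G[2, 2] = 1.0
        fv = haralick_features(GLCMatrix(G))
        assert fv["contrast"] == pytest.approx(0.0, abs=1e-12)
        assert fv["dissimilarity"] == pytest.approx(0.0, abs=1e-12)
        assert fv["energy"] == pytest.approx(1.0, abs=1e-12)
        assert fv["entropy"] == pytest.approx(0.0, abs=1e-12)
        assert fv["homogeneity"] == pytest.approx(1.0, abs=1e-12)
        assert fv["maximum_probability"] == pytest.approx(1.0, abs=1e-12)

    def test_uniform_two_level_closed_forms(self):
        G = np.full((2, 2), 0.25)
        fv = haralick_features(GLCMatrix(G))
        assert fv["energy"] == pytest.approx(0.25, abs=1e-12)
        assert fv["contrast"] == pytest.approx(0.5, abs=1e-12)
        assert fv["entropy"] == pytest.approx(np.log(4), abs=1e-12)

    @pytest.mark.parametrize("levels", [2, 3, 4, 6])
    def test_matches_literal_oracle(self, levels, rng):
        for _ in range(10):
            G = random_symmetric_glcm(rng, levels)
            fv = haralick_features(GLCMatrix(G))
            ref = reference_features(G)
            for name in FEATURE_NAMES:
                assert fv[name] == pytest.approx(ref[name], abs=1e-10), name

    def test_central_difference_variance_flag(self, rng):
        G = random_symmetric_glcm(rng, 4)
        fv = haralick_features(GLCMatrix(G), central_difference_variance=True)
        ref = reference_features(G, central_difference_variance=True)
        assert fv["difference_variance"] == pytest.approx(
            ref["difference_variance"], abs=1e-10
        )

    def test_all_finite_and_bounded(self, rng):
        for _ in range(30):
            G = random_symmetric_glcm(rng, int(rng.integers(2, 9)))
            fv = haralick_features(GLCMatrix(G))
            assert np.isfinite(fv.values).all()
            assert 0 <= fv["energy"] <= 1
            assert 0 <= fv["maximum_probability"] <= 1
            assert fv["entropy"] >= 0
            assert fv["contrast"] >= 0
            assert fv["dissimilarity"] >= 0
            assert 0 < fv["homogeneity"] <= 1

    def test_marginal_distributions_sum_to_one(self, rng):
        for _ in range(20):
            G = random_symmetric_glcm(rng, int(rng.integers(2, 9)))
            m = marginals(GLCMatrix(G))
            assert m.p_sum.sum() == pytest.approx(1.0, abs=1e-12)
            assert m.p_diff.sum() == pytest.approx(1.0, abs=1e-12)
            assert m.sigma_x >= 0 and m.sigma_y >= 0

    def test_batch_matches_single(self, rng):
        Gs = np.stack([random_symmetric_glcm(rng, 5) for _ in range(8)])
        batch = _features_batch(Gs)
        for k in range(8):
            single = haralick_features(GLCMatrix(Gs[k])).values
            np.testing.assert_allclose(batch[:, k], single, atol=1e-13)


class TestFeatureMaps:
    def test_constant_slice(self):
        data = np.full((9, 9), 5.0)
        fm = feature_maps(data, np.ones((9, 9), bool), window_size=3, levels=4)
        i_contrast = FEATURE_NAMES.index("contrast")
        i_energy = FEATURE_NAMES.index("energy")
        np.testing.assert_allclose(fm[i_contrast], 0.0, atol=1e-12)
        np.testing.assert_allclose(fm[i_energy], 1.0, atol=1e-12)

    def test_interior_matches_single_window(self, rng):
        # two-texture half plane; a pixel deep inside one half sees only
        # that texture, so its features equal the isolated-window result
        data = np.zeros((21, 21))
        data[:, :10] = rng.integers(0, 3, size=(21, 10)).astype(float)
        data[:, 10:] = rng.integers(5, 8, size=(21, 11)).astype(float)
        mask = np.ones((21, 21), bool)
        w, N = 5, 8
        fm = feature_maps(data, mask, window_size=w, levels=N)
        r, c = 10, 4  # window [8:13, 2:7] fully in the left half
        qs = quantize(data, mask, N)
        win = QuantizedSlice(qs.data[8:13, 2:7], levels=N)
        fv = haralick_features(compute_glcm(win))
        np.testing.assert_allclose(fm[:, r, c], fv.values, atol=1e-12)

    def test_masked_out_pixels_do_not_leak(self, rng):
        data = rng.random((12, 12)) * 100
        mask = np.ones((12, 12), bool)
        mask[:, :6] = False
        fm1 = feature_maps(data, mask, window_size=5, levels=6)
        data2 = data.copy()
        data2[:, :6] = rng.random((12, 6)) * 1000  # perturb excluded half
        fm2 = feature_maps(data2, mask, window_size=5, levels=6)
        np.testing.assert_array_equal(
            np.nan_to_num(fm1, nan=-1), np.nan_to_num(fm2, nan=-1)
        )

    def test_unmasked_pixels_are_nan(self, rng):
        data = rng.random((8, 8))
        mask = np.zeros((8, 8), bool)
        mask[2:6, 2:6] = True
        fm = feature_maps(data, mask, window_size=3, levels=4)
        assert np.isnan(fm[:, 0, 0]).all()
        assert np.isfinite(fm[:, 3, 3]).all()

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            feature_maps(np.zeros((5, 5)), np.ones((5, 5), bool), window_size=4)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            feature_maps(np.zeros((5, 5)), np.zeros((5, 5), bool))
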