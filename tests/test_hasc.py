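"""HASC descriptors: joint histograms, entropy/MI identities, EMI/COV, tiling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from dissimspace.data import LabeledImage
from dissimspace.hasc import (cov_matrix, emi_matrix, entropy, hasc_descriptor,
                              hasc_image, hasc_mosaic, joint_histogram,
                              low_level_features, mutual_information)

finite_vectors = hnp.arrays(
    np.float64, st.integers(5, 60),
    elements=st.floats(-50, 50, allow_nan=False, allow_infinity=False))


class TestLowLevelFeatures:
    def test_depth_is_six(self, rng):
        img = LabeledImage(rng.random((12, 15)), 0)
        assert low_level_features(img).values.shape == (12, 15, 6)

    def test_constant_image_has_zero_derivative_maps(self):
        stack = low_level_features(LabeledImage(np.full((8, 8), 0.7), 0))
        assert np.allclose(stack.values[:, :, 0], 0.7)
        for i in range(1, 6):
            assert np.allclose(stack.map(i), 0.0)

    def test_horizontal_ramp_has_zero_vertical_derivative(self):
        ramp = np.tile(np.linspace(0, 1, 10), (8, 1))
        stack = low_level_features(LabeledImage(ramp, 0))
        assert np.allclose(stack.map(2), 0.0)  # |d/dy|
        assert np.all(stack.map(1) > 0)        # |d/dx| of a ramp

    def test_rejects_tiny_images(self):
        with pytest.raises(ValueError):
            low_level_features(LabeledImage(np.zeros((2, 10)), 0))


class TestJointHistogram:
    def test_normalized_and_marginals_match_1d(self, rng):
        a, b = rng.random(200), rng.random(200)
        jh = joint_histogram(a, b, bins=8)
        assert jh.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        marg_a, _ = np.histogram(a, bins=jh.bin_edges_a)
        marg_b, _ = np.histogram(b, bins=jh.bin_edges_b)
        np.testing.assert_allclose(jh.probabilities.sum(axis=1), marg_a / 200)
        np.testing.assert_allclose(jh.probabilities.sum(axis=0), marg_b / 200)

    def test_constant_pair_concentrates_in_one_bin(self):
        jh = joint_histogram(np.full(9, 3.0), np.full(9, 3.0), bins=4)
        assert np.count_nonzero(jh.probabilities) == 1
        assert jh.probabilities.max() == pytest.approx(1.0)

    def test_two_point_diagonal(self):
        # pairs (0,0) and (1,1) with 2 bins land on the diagonal, mass 1/2 each
        jh = joint_histogram(np.array([0.0, 1.0]), np.array([0.0, 1.0]), bins=2)
        np.testing.assert_allclose(jh.probabilities, [[0.5, 0.0], [0.0, 0.5]])

    def test_errors(self):
        with pytest.raises(ValueError):
            joint_histogram(np.zeros(3), np.zeros(4), bins=2)
        with pytest.raises(ValueError):
            joint_histogram(np.zeros(3), np.zeros(3), bins=0)


class TestEntropyMI:
    def test_constant_vector_has_zero_entropy(self):
        assert entropy(np.full(50, 2.5), bins=8) == 0.0

    @pytest.mark.parametrize("bins", [2, 5, 16])
    def test_uniform_bin_filling_gives_log_bins(self, bins):
        # one value per bin center -> uniform over bins -> entropy log(B)
        a = (np.arange(bins) + 0.5) / bins
        assert entropy(a, bins=bins) == pytest.approx(np.log(bins), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(finite_vectors, st.integers(1, 12))
    def test_self_mi_equals_entropy(self, a, bins):
        assert mutual_information(a, a, bins) == pytest.approx(
            entropy(a, bins), abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(finite_vectors, st.integers(2, 12))
    def test_mi_nonnegative_and_symmetric(self, a, bins):
        rng = np.random.default_rng(0)
        b = rng.permutation(a)
        mab = mutual_information(a, b, bins)
        assert mab >= 0.0
        assert mab == pytest.approx(mutual_information(b, a, bins), abs=1e-9)

    def test_independent_uniforms_give_near_zero_mi(self):
        rng = np.random.default_rng(123)
        a, b = rng.random(100_000), rng.random(100_000)
        assert mutual_information(a, b, bins=8) < 0.02

    def test_constant_marginal_gives_zero_mi(self, rng):
        assert mutual_information(np.full(30, 1.0), rng.random(30), 8) == 0.0


class TestRelationalMatrices:
    def test_constant_stack_gives_zero_emi_and_cov(self):
        img = LabeledImage(np.full((10, 10), 0.3), 0)
        stack = low_level_features(img)
        assert np.allclose(emi_matrix(stack, 8).entries, 0.0)
        assert np.allclose(cov_matrix(stack).entries, 0.0)

    def test_emi_diagonal_equals_map_entropies(self, rng):
        img = LabeledImage(rng.random((14, 14)), 0)
        stack = low_level_features(img)
        emi = emi_matrix(stack, bins=10)
        for i in range(6):
            assert emi.entries[i, i] == pytest.approx(
                entropy(stack.map(i).ravel(), 10), abs=1e-12)

    def test_duplicated_map_mi_equals_entropy(self, rng):
        # brute-force oracle: MI of a map with itself is its entropy
        from dissimspace.hasc import FeatureStack
        base = rng.random((9, 9))
        maps = [base, base] + [rng.random((9, 9)) for _ in range(4)]
        stack = FeatureStack(np.stack(maps, axis=2))
        emi = emi_matrix(stack, bins=6)
        assert emi.entries[0, 1] == pytest.approx(
            entropy(base.ravel(), 6), abs=1e-9)

    def test_cov_hand_computed_two_pixels(self):
        from dissimspace.hasc import FeatureStack
        # maps m1=[0,2], m2=[0,4] over 2 pixels: cov = (0*0 + 2*4)/(2-1)/2... by
        # definition sum((x-mx)(y-my))/(n-1) = (1*2 + 1*2)/1 = 4
        vals = np.zeros((1, 2, 2))
        vals[0, :, 0] = [0.0, 2.0]
        vals[0, :, 1] = [0.0, 4.0]
        cov = cov_matrix(FeatureStack(vals))
        assert cov.entries[0, 1] == pytest.approx(4.0)

    def test_cov_is_psd(self, rng):
        img = LabeledImage(rng.random((16, 16)), 0)
        cov = cov_matrix(low_level_features(img))
        assert np.linalg.eigvalsh(cov.entries).min() >= -1e-8


class TestDescriptor:
    def test_length_is_72(self, rng):
        img = LabeledImage(rng.random((12, 12)), 0)
        assert hasc_descriptor(img, bins=8).vector.shape == (72,)

    def test_constant_image_gives_zero_descriptor(self):
        desc = hasc_descriptor(LabeledImage(np.full((10, 10), 0.5), 0), bins=8)
        assert np.allclose(desc.vector, 0.0)

    def test_matches_concatenation_oracle(self, rng):
        for _ in range(10):
            img = LabeledImage(rng.random((11, 13)), 0)
            stack = low_level_features(img)
            expected = np.concatenate([emi_matrix(stack, 8).entries.ravel(),
                                       cov_matrix(stack).entries.ravel()])
            np.testing.assert_allclose(
                hasc_descriptor(img, bins=8).vector, expected)


class TestHascImage:
    def test_mosaic_is_3h_by_2w(self, rng):
        img = LabeledImage(rng.random((10, 14)), 0)
        assert hasc_mosaic(img).shape == (30, 28)

    def test_default_output_is_224(self, rng):
        out = hasc_image(LabeledImage(rng.random((10, 10)), 3))
        assert out.pixels.shape == (224, 224)
        assert out.label == 3

    def test_constant_image_yields_uniform_derivative_tiles(self):
        mosaic = hasc_mosaic(LabeledImage(np.full((8, 8), 0.4), 0))
        tiles = [mosaic[r * 8:(r + 1) * 8, c * 8:(c + 1) * 8]
                 for r in range(3) for c in range(2)]
        uniform = [np.ptp(t) == 0 for t in tiles]
        assert sum(uniform) == 6  # intensity tile is constant too

    def test_invalid_out_size(self, rng):
        with pytest.raises(ValueError):
            hasc_image(LabeledImage(rng.random((8, 8)), 0), out_size=0)
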