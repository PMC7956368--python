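"""Backbone catalog arithmetic, the subtract block, and pair-score symmetry."""

import numpy as np
import pytest

from dissimspace.data import LabeledImage
from dissimspace.reference import REFERENCE_TABLE, reference_param_checks
from dissimspace.siamese import (ArchitectureSpec, build_model, catalog,
                                 count_parameters, get_architecture,
                                 infer_shapes, leaky_relu, scale_architecture,
                                 score_pair, subtract_block, total_parameters)


class TestCatalog:
    def test_exactly_eight_topologies(self):
        specs = catalog()
        assert [s.id for s in specs] == list(range(1, 9))

    def test_network_2_embeds_to_2048(self):
        assert get_architecture(2).embedding_dim == 2048
        assert all(get_architecture(i).embedding_dim == 4096
                   for i in (1, 3, 4, 5, 6, 7, 8))

    def test_network_7_starts_with_dropout(self):
        assert get_architecture(7).layers[1].kind == "dropout"

    def test_network_8_has_two_grouped_convolutions(self):
        kinds = [l.kind for l in get_architecture(8).layers]
        assert kinds.count("grouped_conv") == 2
        assert all(l.groups == 2 for l in get_architecture(8).layers
                   if l.kind == "grouped_conv")

    def test_json_round_trip(self):
        spec = get_architecture(3)
        again = ArchitectureSpec.from_json(spec.to_json())
        assert again == spec


class TestShapeArithmetic:
    def test_first_convolutions(self):
        shapes1 = infer_shapes(get_architecture(1))
        assert shapes1[1] == (215, 215, 64)
        shapes3 = infer_shapes(get_architecture(3))
        assert shapes3[1] == (55, 55, 128)  # stride-4 convolution

    def test_pooling_floors(self):
        # 2x2 stride-2 pool on 215 -> 107
        assert infer_shapes(get_architecture(1))[3][:2] == (107, 107)

    @pytest.mark.parametrize("arch_id", [1, 2, 3, 4, 6, 7, 8])
    def test_published_activations_reproduced(self, arch_id):
        shapes = infer_shapes(get_architecture(arch_id))
        for computed, (kind, published, _) in zip(shapes, REFERENCE_TABLE[arch_id]):
            assert tuple(computed) == tuple(published), (arch_id, kind)


class TestParameterArithmetic:
    def test_first_conv_counts(self):
        # 10x10 single-channel conv with 64 filters
        from dissimspace.siamese import LayerSpec
        conv = LayerSpec("conv", filter_size=10, num_filters=64)
        assert count_parameters(conv, 1) == 6464

    def test_one_by_one_conv(self):
        from dissimspace.siamese import LayerSpec
        conv = LayerSpec("conv", filter_size=1, num_filters=64)
        assert count_parameters(conv, 128) == 8256

    def test_fully_connected_count(self):
        from dissimspace.siamese import LayerSpec
        fc = LayerSpec("fully_connected", out_units=4096)
        assert count_parameters(fc, 64, (19, 19, 64)) == 94_638_080

    @pytest.mark.parametrize("arch_id", range(1, 9))
    def test_published_counts_reproduced(self, arch_id):
        for layer_idx, computed, published in reference_param_checks(arch_id):
            assert computed == published, (arch_id, layer_idx)

    def test_total_parameters_runs(self):
        assert total_parameters(get_architecture(3)) > 2_000_000


class TestActivationsAndBlocks:
    def test_leaky_relu_branches(self):
        assert leaky_relu(3.0, 0.5) == 3.0
        assert leaky_relu(-2.0, 0.01) == pytest.approx(-0.02)
        # zero slope reduces to plain ReLU
        assert leaky_relu(-7.0, 0.0) == 0.0

    def test_subtract_block_values_and_symmetry(self, rng):
        f1, f2 = np.array([1.0, -2.0]), np.array([0.0, 1.0])
        np.testing.assert_allclose(subtract_block(f1, f2), [1.0, 3.0])
        a, b = rng.normal(size=30), rng.normal(size=30)
        np.testing.assert_array_equal(subtract_block(a, b), subtract_block(b, a))
        assert np.allclose(subtract_block(a, a), 0.0)
        with pytest.raises(ValueError):
            subtract_block(np.zeros(3), np.zeros(4))


class TestPairScoring:
    def test_score_symmetric_over_random_weights(self, rng, tiny_arch):
        arch = tiny_arch
        for seed in range(10):
            model = build_model(arch, seed=seed)
            x = LabeledImage(rng.random((20, 20)), 0)
            y = LabeledImage(rng.random((20, 20)), 1)
            s_xy, s_yx = score_pair(model, x, y), score_pair(model, y, x)
            assert s_xy == pytest.approx(s_yx, abs=1e-6)
            assert 0.0 < s_xy < 1.0

    def test_identical_inputs_score_half_with_zero_bias(self, rng, tiny_arch):
        model = build_model(tiny_arch, seed=0)
        x = LabeledImage(rng.random((20, 20)), 0)
        assert score_pair(model, x, x) == pytest.approx(0.5)

    def test_wrong_input_size_rejected(self, rng, tiny_arch):
        model = build_model(tiny_arch, seed=0)
        with pytest.raises(ValueError):
            model.score_batch(rng.random((1, 9, 9)), rng.random((1, 9, 9)))

    def test_save_load_round_trip(self, tmp_path, rng, tiny_arch):
        model = build_model(tiny_arch, seed=1)
        x = rng.random((2, 20, 20))
        y = rng.random((2, 20, 20))
        before = model.score_batch(x, y)
        path = str(tmp_path / "weights.npz")
        model.save(path)
        fresh = build_model(tiny_arch, seed=99)
        fresh.load_weights(path)
        np.testing.assert_allclose(fresh.score_batch(x, y), before)


class TestScaledArchitectures:
    def test_scaling_preserves_pattern_and_fits_input(self):
        arch = scale_architecture(get_architecture(3), 64, 0.25, 64)
        shapes = infer_shapes(arch, 64)
        assert shapes[-1] == (64,)
        assert all(len(s) == 1 or min(s[:2]) >= 1 for s in shapes)

    def test_scaling_shrinks_parameters(self):
        full = total_parameters(get_architecture(3))
        small = total_parameters(scale_architecture(get_architecture(3), 64))
        assert small < full / 50
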