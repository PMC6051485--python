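"""Architecture, receptive-field arithmetic, caching and gradients."""

import numpy as np
import pytest

from boxseg.errors import ConfigurationError, InputError, StateError
from boxseg.networks import (BlockSpec, Network, NetworkSpec, build_network,
                             default_2d_spec, default_3d_spec,
                             receptive_field)


def tiny_2d_spec(channels=2):
    return NetworkSpec(tuple(BlockSpec((3, 3), (d, d), channels, 1)
                             for d in (1, 2, 4, 8, 16)))


class TestReceptiveField:
    def test_single_three_tap_layer(self):
        spec = NetworkSpec(tuple(
            BlockSpec((3, 3), (d, d), 2, 1) for d in (1, 2, 4, 8, 16)))
        # one 3-tap dilation-1 layer contributes 2; the full stack telescopes
        assert receptive_field(spec) == (1 + 2 * (1 + 2 + 4 + 8 + 16),) * 2

    def test_default_2d_matches_published_extent(self):
        assert receptive_field(default_2d_spec()) == (181, 181)

    def test_default_3d_anisotropic_extent(self):
        assert receptive_field(default_3d_spec()) == (85, 85, 9)

    def test_width_does_not_change_receptive_field(self):
        assert receptive_field(default_2d_spec(channels=16)) == (181, 181)


class TestSpecValidation:
    def test_even_kernel_rejected(self):
        blocks = tuple(BlockSpec((4, 3), (d, d), 2, 1) for d in (1, 2, 4, 8, 16))
        with pytest.raises(ConfigurationError, match="odd"):
            NetworkSpec(blocks).validate()

    def test_zero_dilation_rejected(self):
        blocks = (BlockSpec((3, 3), (0, 0), 2, 1),) + tuple(
            BlockSpec((3, 3), (d, d), 2, 1) for d in (2, 4, 8, 16))
        with pytest.raises(ConfigurationError, match="dilation"):
            NetworkSpec(blocks).validate()

    def test_wrong_2d_dilation_ladder_rejected(self):
        blocks = tuple(BlockSpec((3, 3), (d, d), 2, 1) for d in (1, 2, 4, 8, 8))
        with pytest.raises(ConfigurationError, match="dilation"):
            NetworkSpec(blocks).validate()

    def test_3d_kernel_anisotropy_enforced(self):
        blocks = tuple(BlockSpec((3, 3, 3), (1, 1, 1), 2, 1) for _ in range(5))
        with pytest.raises(ConfigurationError, match="3x3x1"):
            NetworkSpec(blocks, compression_channels=4).validate()

    def test_dims_mismatch_rejected(self):
        with pytest.raises(ConfigurationError, match="dims"):
            build_network(default_2d_spec(channels=2), dims=3)

    def test_spec_json_roundtrip(self):
        spec = default_3d_spec(channels=2, compression_channels=3)
        again = NetworkSpec.from_json(spec.to_json())
        assert again == spec and again.hash() == spec.hash()


class TestForward:
    @pytest.mark.parametrize("shape", [(96, 96), (37, 53), (9, 8)])
    def test_resolution_preserving_2d(self, shape, rng):
        net = build_network(tiny_2d_spec(), seed=0)
        p = net.forward_probability(rng.standard_normal(shape)).p
        assert p.shape == shape
        assert np.all((p >= 0) & (p <= 1))

    def test_resolution_preserving_3d(self, rng):
        net = build_network(default_3d_spec(channels=2, compression_channels=2), seed=0)
        x = rng.standard_normal((5, 11, 9))
        assert net.forward_probability(x).p.shape == x.shape

    def test_zeroed_classifier_gives_half(self, rng):
        net = build_network(tiny_2d_spec(), seed=0)
        net.classifier.weight[:] = 0
        net.classifier.bias[:] = 0
        p = net.forward_probability(rng.standard_normal((12, 13))).p
        assert np.allclose(p, 0.5)

    def test_forward_deterministic(self, rng):
        net = build_network(tiny_2d_spec(), seed=3)
        x = rng.standard_normal((20, 17))
        assert np.array_equal(net.forward_probability(x).p,
                              net.forward_probability(x).p)

    def test_dimensionality_mismatch_raises(self, rng):
        net = build_network(tiny_2d_spec(), seed=0)
        with pytest.raises(InputError):
            net.forward_probability(rng.standard_normal((4, 4, 4)))

    def test_trained_net_separates_bright_blob(self, toy_net, toy_benchmark):
        inst = toy_benchmark.train_instances[0]
        p = toy_net.forward_probability(inst.region.intensities).p
        fg = inst.mask.astype(bool)
        assert p[fg].mean() > p[~fg].mean()


class TestFeatureCache:
    def test_cache_forward_bitwise_equal(self, rng):
        net = build_network(tiny_2d_spec(), seed=1)
        x = rng.standard_normal((15, 18))
        full = net.forward_probability(x).p
        cached = net.probability_from_cache(net.cache_features(x)).p
        assert np.array_equal(full, cached)

    def test_backbone_perturbation_staleness(self, rng):
        net = build_network(tiny_2d_spec(), seed=1)
        x = rng.standard_normal((10, 10))
        cache = net.cache_features(x)
        net.blocks[0][0].weight += 0.1
        # cached result no longer matches a full forward, and is detectable
        assert not np.allclose(net.forward_probability(x).p,
                               net.probability_from_cache(cache).p)
        with pytest.raises(StateError):
            net.check_cache(cache)

    def test_classifier_perturbation_keeps_cache_valid(self, rng):
        net = build_network(tiny_2d_spec(), seed=1)
        x = rng.standard_normal((10, 10))
        cache = net.cache_features(x)
        net.classifier.weight = net.classifier.weight + 0.3
        net.check_cache(cache)  # backbone untouched
        assert np.array_equal(net.forward_probability(x).p,
                              net.probability_from_cache(cache).p)

    def test_classifier_params_disjoint_from_backbone(self):
        net = build_network(default_3d_spec(channels=2, compression_channels=2), seed=0)
        cls = set(net.classifier_parameter_names())
        assert cls == {"block6/conv0/W", "block6/conv0/b"}
        assert cls.isdisjoint(set(net.parameters()) - cls)


class TestBackprop:
    def test_gradients_match_finite_differences(self, rng):
        # float64 net with biases nudged off the ReLU kinks
        net = Network(tiny_2d_spec(), seed=2, dtype=np.float64)
        params = net.parameters()
        for k, v in params.items():
            if k.endswith("/b"):
                v += rng.normal(0, 0.1, v.shape)
        x = rng.standard_normal((9, 8))
        y = (rng.random((9, 8)) > 0.5).astype(float)
        w = rng.random((9, 8))
        _, grads = net.backprop(x, y, w, reduction="sum")
        for name, arr in params.items():
            for _ in range(3):
                idx = tuple(rng.integers(s) for s in arr.shape)
                eps, orig = 1e-6, arr[idx]
                arr[idx] = orig + eps
                lp, _ = net.backprop(x, y, w, "sum")
                arr[idx] = orig - eps
                lm, _ = net.backprop(x, y, w, "sum")
                arr[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[name][idx] == pytest.approx(num, rel=1e-4, abs=1e-7)

    def test_gradients_3d_compression_path(self, rng):
        net = Network(default_3d_spec(channels=2, compression_channels=3),
                      seed=5, dtype=np.float64)
        params = net.parameters()
        for k, v in params.items():
            if k.endswith("/b"):
                v += rng.normal(0, 0.1, v.shape)
        x = rng.standard_normal((4, 7, 6))
        y = (rng.random((4, 7, 6)) > 0.5).astype(float)
        _, grads = net.backprop(x, y, None, reduction="mean")
        for name in ("block2/compress/W", "block1/conv0/W", "block5/conv2/b"):
            arr = params[name]
            idx = tuple(rng.integers(s) for s in arr.shape)
            eps, orig = 1e-6, arr[idx]
            arr[idx] = orig + eps
            lp, _ = net.backprop(x, y, None, "mean")
            arr[idx] = orig - eps
            lm, _ = net.backprop(x, y, None, "mean")
            arr[idx] = orig
            assert grads[name][idx] == pytest.approx((lp - lm) / (2 * eps),
                                                     rel=1e-4, abs=1e-8)
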