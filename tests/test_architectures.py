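"""Network building blocks against independent scalar-loop oracles."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleikit import architectures as arch
from nucleikit.nn import Tensor, no_grad

from oracles import conv2d_scalar, recurrent_conv_scalar

TOL = 1e-5


def _randomize_bn(layer_bn, r):
    """Give BN non-trivial eval-mode statistics so the oracle is exercised."""
    layer_bn.gamma.data = r.uniform(0.5, 1.5, layer_bn.channels).astype(np.float32)
    layer_bn.beta.data = r.normal(0, 0.2, layer_bn.channels).astype(np.float32)
    layer_bn.running_mean = r.normal(0, 0.3, layer_bn.channels).astype(np.float32)
    layer_bn.running_var = r.uniform(0.5, 2.0, layer_bn.channels).astype(np.float32)


class TestRecurrentConvLayer:
    @pytest.mark.parametrize("t", [0, 1, 2, 3])
    @pytest.mark.parametrize("mode,kernel", [
        ("shared", "full"), ("distinct", "full"), ("distinct", "depthwise")])
    def test_matches_scalar_unrolling_oracle(self, rng, t, mode, kernel):
        cfg = arch.RCLConfig(out_channels=4, time_steps=t, weight_mode=mode,
                             recurrent_kernel=kernel)
        layer = arch.RecurrentConvLayer(3, cfg, rng)
        _randomize_bn(layer.bn, rng)
        x = rng.normal(0, 1, (1, 8, 8, 3)).astype(np.float32)
        layer.eval()
        with no_grad():
            got = layer(Tensor(x)).data
        n_kernels = 0 if t == 0 else (1 if mode == "shared" else t)
        recs = [layer.recurrent[min(s, n_kernels - 1)].weight.data
                for s in range(t)]
        want = recurrent_conv_scalar(
            x.astype(np.float64), layer.bn.gamma.data, layer.bn.beta.data,
            layer.bn.running_mean, layer.bn.running_var,
            layer.conv_f.weight.data, layer.conv_f.bias.data, recs,
            depthwise=(kernel == "depthwise"))
        assert got.shape == (1, 8, 8, 4)
        np.testing.assert_allclose(got, want, atol=TOL)

    def test_t_zero_equals_plain_bn_relu_conv(self, rng):
        cfg0 = arch.RCLConfig(out_channels=5, time_steps=0)
        layer = arch.RecurrentConvLayer(2, cfg0, np.random.default_rng(7))
        x = rng.normal(0, 1, (2, 6, 6, 2)).astype(np.float32)
        layer.eval()
        with no_grad():
            got = layer(Tensor(x)).data
        a = np.maximum(x / np.sqrt(1 + 1e-5), 0)  # eval BN with default stats
        want = conv2d_scalar(a.astype(np.float64), layer.conv_f.weight.data,
                             layer.conv_f.bias.data)
        np.testing.assert_allclose(got, want, atol=TOL)

    def test_zero_recurrent_weights_make_output_t_independent(self, rng):
        x = rng.normal(0, 1, (1, 6, 6, 3)).astype(np.float32)
        outs = []
        for t in (1, 2, 3):
            cfg = arch.RCLConfig(out_channels=4, time_steps=t,
                                 weight_mode="distinct")
            layer = arch.RecurrentConvLayer(3, cfg, np.random.default_rng(0))
            for rec in layer.recurrent:
                rec.weight.data[:] = 0.0
            layer.eval()
            with no_grad():
                outs.append(layer(Tensor(x)).data)
        np.testing.assert_allclose(outs[0], outs[1], atol=TOL)
        np.testing.assert_allclose(outs[0], outs[2], atol=TOL)

    def test_negative_time_steps_rejected(self):
        with pytest.raises(ValueError):
            arch.RCLConfig(out_channels=4, time_steps=-1)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            arch.RCLConfig(out_channels=4, kernel_size=4)

    def test_channel_mismatch_rejected(self, rng):
        layer = arch.RecurrentConvLayer(3, arch.RCLConfig(out_channels=4), rng)
        layer.eval()
        bad = Tensor(rng.normal(size=(1, 4, 4, 5)).astype(np.float32))
        with pytest.raises(ValueError):
            with no_grad():
                layer(bad)


class TestRecurrentResidualUnit:
    def test_zero_branch_weights_give_exact_identity(self, rng):
        cfg = arch.RCLConfig(out_channels=3, time_steps=2)
        unit = arch.RecurrentResidualUnit(3, cfg, rng=np.random.default_rng(0))
        for _, p in unit.named_parameters():
            if p.ndim >= 3:        # conv kernels
                p.data[:] = 0.0
        for layer in unit.layers:
            layer.conv_f.bias.data[:] = 0.0
        x = rng.normal(0, 1, (2, 5, 7, 3)).astype(np.float32)
        unit.eval()
        with no_grad():
            out = unit(Tensor(x)).data
        np.testing.assert_allclose(out, x, atol=1e-6)

    @pytest.mark.parametrize("h,w", [(4, 4), (5, 9), (8, 3)])
    def test_shape_preserved_for_any_spatial_size(self, rng, h, w):
        cfg = arch.RCLConfig(out_channels=6, time_steps=2)
        out = arch.recurrent_residual_unit(
            rng.normal(0, 1, (1, h, w, 2)).astype(np.float32), cfg, seed=3)
        assert out.shape == (1, h, w, 6)

    def test_matches_input_plus_oracle_branch(self, rng):
        cfg = arch.RCLConfig(out_channels=2, time_steps=2)
        unit = arch.RecurrentResidualUnit(2, cfg, n_layers=2,
                                          rng=np.random.default_rng(11))
        for layer in unit.layers:
            _randomize_bn(layer.bn, rng)
        x = rng.normal(0, 1, (1, 4, 4, 2)).astype(np.float32)
        unit.eval()
        with no_grad():
            got = unit(Tensor(x)).data
        h = x.astype(np.float64)
        for layer in unit.layers:
            h = recurrent_conv_scalar(
                h, layer.bn.gamma.data, layer.bn.beta.data,
                layer.bn.running_mean, layer.bn.running_var,
                layer.conv_f.weight.data, layer.conv_f.bias.data,
                [layer.recurrent[0].weight.data] * 2)
        np.testing.assert_allclose(got, x + h, atol=TOL)


class TestDenseRecurrentBlock:
    def test_growth12_block_channel_count(self, rng):
        cfg = arch.DenseBlockConfig(input_channels=24, num_layers=7, growth_rate=12,
                                    time_steps=0)
        out = arch.dense_recurrent_block(
            rng.normal(0, 1, (1, 8, 8, 24)).astype(np.float32), cfg)
        assert out.shape[-1] == 24 + 7 * 12 == 108

    def test_empty_block_is_identity(self, rng):
        cfg = arch.DenseBlockConfig(input_channels=5, num_layers=0)
        x = rng.normal(0, 1, (1, 4, 4, 5)).astype(np.float32)
        np.testing.assert_array_equal(arch.dense_recurrent_block(x, cfg), x)

    def test_growth_rate_formula_for_internal_layers(self):
        cfg = arch.DenseBlockConfig(input_channels=24, growth_rate=12, num_layers=7)
        block = arch.DenseRecurrentBlock(cfg)
        # layer l receives k*(l-1) + k0 input feature maps
        for l, layer in enumerate(block.layers, start=1):
            assert layer.in_channels == 12 * (l - 1) + 24
        assert block.layers[2].in_channels == 48  # l = 3 worked example

    @given(k0=st.integers(1, 40), L=st.integers(0, 8), k=st.integers(1, 16))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_channel_conservation_property(self, k0, L, k):
        cfg = arch.DenseBlockConfig(input_channels=k0, num_layers=L, growth_rate=k,
                                    time_steps=0)
        x = np.zeros((1, 4, 4, k0), np.float32)
        assert arch.dense_recurrent_block(x, cfg).shape[-1] == k0 + L * k

    def test_input_channel_mismatch_rejected(self):
        cfg = arch.DenseBlockConfig(input_channels=8)
        with pytest.raises(ValueError):
            arch.dense_recurrent_block(np.zeros((1, 4, 4, 5), np.float32), cfg)


class TestTransitionBlock:
    def test_spatial_halving_and_channel_mapping(self, rng):
        out = arch.transition_block(
            rng.normal(0, 1, (1, 32, 32, 96)).astype(np.float32), 96)
        assert out.shape == (1, 16, 16, 96)

    def test_identity_conv_preserves_constant_plane(self):
        block = arch.TransitionBlock(1, 1)
        block.conv.weight.data[:] = 1.0
        block.conv.bias.data[:] = 0.0
        x = np.full((1, 8, 8, 1), 3.0, np.float32)
        block.eval()
        with no_grad():
            out = block(Tensor(x)).data
        const = 3.0 / np.sqrt(1 + 1e-5)  # eval-mode BN scaling
        np.testing.assert_allclose(out, const, atol=1e-5)

    def test_average_pooling_of_ramp(self):
        block = arch.TransitionBlock(1, 1)
        block.conv.weight.data[:] = 1.0
        block.conv.bias.data[:] = 0.0
        block.bn.running_var[:] = 1.0 - 1e-5  # unit-scale eval BN
        x = np.arange(64, dtype=np.float32).reshape(1, 8, 8, 1)
        block.eval()
        with no_grad():
            out = block(Tensor(x)).data[0, :, :, 0]
        expect = x[0, :, :, 0].reshape(4, 2, 4, 2).mean(axis=(1, 3))
        np.testing.assert_allclose(out, expect, atol=1e-5)

    def test_odd_spatial_dims_rejected(self, rng):
        with pytest.raises(ValueError):
            arch.transition_block(rng.normal(0, 1, (1, 7, 8, 4)).astype(np.float32), 4)


class TestBuildModel:
    @pytest.mark.parametrize("variant,published", [
        ("densenet", 1.228), ("dcrn", 1.228), ("r2unet", 0.983), ("udnet", 1.038)])
    def test_parameter_counts_near_published_totals(self, variant, published):
        n = arch.count_parameters(arch.build_model(variant))
        assert n / 1e6 == pytest.approx(published, rel=0.02)

    def test_calibrated_counts_are_frozen(self):
        expected = {"densenet": 1_227_996, "dcrn": 1_227_996,
                    "r2unet": 983_268, "udnet": 1_041_923}
        for variant, n in expected.items():
            assert arch.count_parameters(arch.build_model(variant)) == n

    def test_densenet_and_dcrn_counts_are_equal(self):
        assert arch.count_parameters(arch.build_model("densenet")) == \
            arch.count_parameters(arch.build_model("dcrn"))

    def test_classifier_softmax_rows_normalised(self, rng):
        model = arch.build_model("dcrn")
        probs = model.predict_proba(rng.random((5, 32, 32, 3), dtype=np.float32))
        assert probs.shape == (5, 4)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    @pytest.mark.parametrize("variant", ["r2unet", "udnet"])
    @pytest.mark.parametrize("side", [16, 32])
    def test_codec_output_matches_input_spatial_dims(self, rng, variant, side):
        model = arch.build_model(variant)
        out = model.predict_map(rng.random((1, side, side, 1), dtype=np.float32))
        assert out.shape == (1, side, side)
        assert (out >= 0).all() and (out <= 1).all()

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            arch.model_spec("segnet")
        with pytest.raises(ValueError):
            arch.ModelSpec(variant="vgg")

    def test_asymmetric_schedule_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            arch.model_spec("r2unet",
                            channel_schedule=(1, 32, 64, 128, 64, 16, 1))

    def test_parameter_count_strictly_increases_with_growth_rate(self):
        counts = [arch.count_parameters(arch.build_model(
            arch.model_spec("densenet", growth_rate=k))) for k in (6, 12, 18)]
        assert counts[0] < counts[1] < counts[2]

    def test_parameter_count_strictly_increases_with_schedule_width(self):
        narrow = arch.model_spec("r2unet",
                                 channel_schedule=(1, 16, 32, 64, 128, 64, 32, 16, 1))
        wide = arch.model_spec("r2unet")
        assert arch.count_parameters(arch.build_model(narrow)) < \
            arch.count_parameters(arch.build_model(wide))

    def test_same_seed_builds_are_bit_identical(self, rng):
        x = rng.random((1, 16, 16, 1), dtype=np.float32)
        a = arch.build_model(arch.model_spec("r2unet", seed=5))
        b = arch.build_model(arch.model_spec("r2unet", seed=5))
        assert arch.count_parameters(a) == arch.count_parameters(b)
        np.testing.assert_array_equal(a.predict_map(x), b.predict_map(x))

    def test_frozen_model_counts_zero_trainable(self):
        model = arch.build_model("densenet")
        for p in model.parameters():
            p.requires_grad = False
        assert arch.count_parameters(model) == 0


class TestCountParameters:
    def test_single_conv_with_bias(self):
        from nucleikit.nn import Conv2d
        assert Conv2d(1, 8, 3, bias=True).trainable_parameter_count == 80
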