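"""Network specs, receptive fields, AdaIN and the mapping network."""

import numpy as np
import pytest

from modgan.nn import (LATENT_DIM, MappingNetwork, PatchDiscriminator,
                       StyleEnhancer, Tensor, UNetGenerator, adain,
                       build_module1_generator, build_module2_generator,
                       build_patch_discriminator, propagate_shapes,
                       receptive_field, receptive_field_footprint)
from modgan.nn.specs import LatentVector, LayerSpec, NetworkSpec


class TestModule1Spec:
    def test_encoder_has_eight_conv_layers_at_full_scale(self):
        spec = build_module1_generator()
        enc = [l for l in spec.layers if l.kind == "conv"]
        assert len(enc) == 8
        assert [l.filters for l in enc] == [64, 128, 256, 512, 512, 512, 512, 512]
        assert all(l.kernel == 4 and l.stride == 2 for l in enc)

    def test_bottleneck_reaches_one_pixel(self):
        spec = build_module1_generator()
        shapes = propagate_shapes(spec)
        assert shapes[7][:2] == (1, 1)  # after the 8th encoder layer
        assert shapes[-1] == (256, 256, 3)

    def test_decoder_mirrors_encoder_with_tanh_output(self):
        spec = build_module1_generator()
        dec = [l for l in spec.layers if l.kind == "transpose_conv"]
        assert [l.filters for l in dec] == [512, 512, 512, 512, 256, 128, 64, 3]
        assert dec[-1].activation == "tanh"

    def test_forward_pass_is_bounded_and_finite(self, rng):
        gen = UNetGenerator(64, width=0.125, rng=rng)
        out = gen(Tensor(np.zeros((1, 3, 64, 64))))
        assert out.shape == (1, 3, 64, 64)
        assert np.isfinite(out.data).all()
        out2 = gen(Tensor(rng.normal(size=(1, 3, 64, 64))))
        assert out2.data.min() >= -1.0 and out2.data.max() <= 1.0

    def test_yaml_round_trip(self):
        spec = build_module1_generator(64)
        again = NetworkSpec.from_yaml(spec.to_yaml())
        assert again == spec


class TestPatchDiscriminator:
    def test_default_spec_structure(self):
        spec = build_patch_discriminator()
        assert spec.extras["hidden_layers"] == 2
        assert [l.filters for l in spec.layers] == [64, 128, 1]
        assert spec.layers[-1].kernel == 1 and spec.layers[-1].stride == 1

    def test_output_is_a_patch_map(self, rng):
        disc = PatchDiscriminator(width=0.125, rng=rng)
        x = Tensor(rng.normal(size=(1, 3, 64, 64)))
        logits, feats = disc(x, x)
        assert logits.shape == (1, 1, 16, 16)  # spatial map, not a scalar
        assert len(feats) == 2

    def test_empty_filter_list_rejected(self):
        with pytest.raises(ValueError):
            build_patch_discriminator([])


class TestReceptiveField:
    def test_single_one_by_one_layer(self):
        spec = NetworkSpec("t", (8, 8, 1), [LayerSpec("conv", 1, 1, 1)])
        assert receptive_field(spec) == 1

    def test_default_discriminator_is_ten(self):
        assert receptive_field(build_patch_discriminator()) == 10

    def test_classic_five_layer_stack_is_seventy(self):
        layers = [LayerSpec("conv", 1, 4, 2)] * 3 + [LayerSpec("conv", 1, 4, 1)] * 2
        spec = NetworkSpec("classic", (128, 128, 1), layers)
        assert receptive_field(spec) == 70

    def test_non_conv_layer_rejected(self):
        spec = NetworkSpec("t", (8, 8, 1), [LayerSpec("transpose_conv", 1, 4, 2)])
        with pytest.raises(ValueError):
            receptive_field(spec)

    @pytest.mark.parametrize("layers,input_size", [
        ([LayerSpec("conv", 1, 3, 1)], 32),
        ([LayerSpec("conv", 1, 4, 2), LayerSpec("conv", 1, 4, 2),
          LayerSpec("conv", 1, 1, 1)], 64),
        ([LayerSpec("conv", 1, 4, 2)] * 3 + [LayerSpec("conv", 1, 4, 1)] * 2, 256),
        ([LayerSpec("conv", 1, 5, 2), LayerSpec("conv", 1, 3, 2)], 64),
    ])
    def test_formula_agrees_with_gradient_footprint(self, layers, input_size):
        spec = NetworkSpec("probe", (input_size, input_size, 1), layers)
        assert receptive_field_footprint(spec, input_size) == receptive_field(spec)


class TestShapePropagation:
    def test_all_built_specs_propagate(self):
        for spec in (build_module1_generator(), build_module1_generator(64),
                     build_patch_discriminator(),
                     build_module2_generator(), build_module2_generator(64)):
            shapes = propagate_shapes(spec)
            assert len(shapes) == len(spec.layers)

    def test_backward_skip_rejected(self):
        spec = build_module1_generator(64)
        spec.skip_connections.append((5, 2))
        with pytest.raises(ValueError):
            propagate_shapes(spec)


class TestAdain:
    def test_identity_style_normalises(self, rng):
        f = Tensor(rng.normal(2.0, 3.0, size=(1, 4, 16, 16)))
        out = adain(f, np.ones(4), np.zeros(4)).data
        assert np.abs(out.mean(axis=(2, 3))).max() < 1e-5
        assert np.abs(out.std(axis=(2, 3)) - 1.0).max() < 1e-3

    def test_scale_and_shift_set_the_moments(self, rng):
        f = Tensor(rng.normal(size=(1, 3, 32, 32)))
        out = adain(f, 2.0 * np.ones(3), 3.0 * np.ones(3)).data
        assert np.abs(out.mean(axis=(2, 3)) - 3.0).max() < 1e-4
        assert np.abs(out.std(axis=(2, 3)) - 2.0).max() < 1e-2

    def test_constant_channel_maps_to_shift(self):
        f = Tensor(np.full((1, 2, 8, 8), 5.0))
        out = adain(f, np.ones(2), np.array([0.7, -0.2])).data
        assert np.isfinite(out).all()
        assert np.allclose(out[0, 0], 0.7) and np.allclose(out[0, 1], -0.2)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            adain(Tensor(rng.normal(size=(1, 4, 8, 8))), np.ones(3), np.zeros(3))


class TestMappingNetwork:
    def test_latent_dimension_enforced(self, rng):
        net = MappingNetwork(rng=rng)
        styles = net(rng.standard_normal((1, LATENT_DIM)))
        assert len(styles) == 2
        with pytest.raises(ValueError):
            net(rng.standard_normal((1, 512)))
        with pytest.raises(ValueError):
            LatentVector(np.zeros(512))

    def test_deterministic_for_fixed_input(self, rng):
        net = MappingNetwork(width=32, channels=32, rng=rng)
        z = rng.standard_normal((1, LATENT_DIM))
        a = net(z)
        b = net(z)
        for (sa, ba), (sb, bb) in zip(a, b):
            assert np.array_equal(sa.data, sb.data)
            assert np.array_equal(ba.data, bb.data)

    def test_distinct_latents_give_distinct_styles(self, rng):
        net = MappingNetwork(width=32, channels=32, rng=rng)
        s1 = net(rng.standard_normal((1, LATENT_DIM)))
        s2 = net(rng.standard_normal((1, LATENT_DIM)))
        assert not np.allclose(s1[0][0].data, s2[0][0].data)


class TestModule2:
    def test_fc_block_depth_is_three(self, rng):
        spec = build_module2_generator()
        assert spec.extras["fc_block"]["n_layers"] == 3
        assert len(MappingNetwork(rng=rng).fc) == 3

    def test_shape_preserving_and_deterministic_in_eval(self, rng):
        gen = StyleEnhancer(64, width=0.0625, rng=rng).eval()
        x = Tensor(rng.normal(size=(1, 3, 64, 64)))
        a = gen(x)
        b = gen(x)
        assert a.shape == (1, 3, 64, 64)
        assert np.array_equal(a.data, b.data)
        assert a.data.min() >= -1.0 and a.data.max() <= 1.0

    def test_style_count_must_match_adain_blocks(self, rng):
        gen = StyleEnhancer(64, width=0.0625, n_adain_blocks=2, rng=rng).eval()
        x = Tensor(rng.normal(size=(1, 3, 64, 64)))
        c = gen.base_channels
        one_style = [(Tensor(np.ones((1, c))), Tensor(np.zeros((1, c))))]
        with pytest.raises(ValueError):
            gen(x, one_style)
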