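"""Structure of the feature extractor: shape arithmetic, residual
behavior, and exact parameter accounting."""

import numpy as np
import pytest

from stripeid import ArchConfig, count_parameters
from stripeid.backbone import (build_backbone, build_block_a, build_block_b,
                               build_block_c, build_reduction_a,
                               build_reduction_b, build_stem,
                               backbone_channels, stem_output_size)
from stripeid.graph import GraphError, ModelGraph

REFERENCE = ArchConfig(n_classes=107)

# Independent stage-by-stage enumeration of the reference dialect:
# convolution weights, residual-projection biases, and the total number of
# batch-normalized channels (each contributing shift + running mean/var).
CONV_WEIGHTS = 54_200_160
PROJECTION_BIASES = 45_760
BN_CHANNELS = 30_272


class TestStem:
    def test_output_shape_299(self):
        g = build_stem(REFERENCE)
        shapes = g.infer_shapes((299, 299, 3))
        assert shapes[g.taps["stem"]] == (35, 35, 192)

    def test_output_shape_75(self):
        g = build_stem(REFERENCE)
        assert g.infer_shapes((75, 75, 3))[g.taps["stem"]] == (7, 7, 192)

    def test_matches_closed_form_chain(self):
        """Shape propagation equals the closed-form stride arithmetic
        (299 -> 149 -> 147 -> 147 -> 73 -> 73 -> 71 -> 35)."""
        g = build_stem(REFERENCE)
        for size in (75, 96, 139, 160, 299):
            side = g.infer_shapes((size, size, 3))[g.taps["stem"]][0]
            assert side == stem_output_size(size)

    def test_too_small_input_rejected_with_minimum(self):
        with pytest.raises(ValueError, match="minimum input_size is 75"):
            ArchConfig(n_classes=10, input_size=10)

    def test_layer_sequence_and_widths(self):
        """conv3/s2, conv3, conv3(same), pool, conv1, conv3, pool with
        widths 32, 32, 64, 80, 192 at multiplier 1."""
        g = build_stem(REFERENCE)
        convs = [s for s in g.specs.values() if s.kind == "conv"]
        assert [c["out_channels"] for c in convs] == [32, 32, 64, 80, 192]
        assert [c["kernel"] for c in convs] == [(3, 3)] * 3 + [(1, 1), (3, 3)]
        assert convs[0]["stride"] == 2
        assert [c.get("padding", "valid") for c in convs] == [
            "valid", "valid", "same", "valid", "valid"]
        assert sum(s.kind == "maxpool" for s in g.specs.values()) == 2


class TestResidualBlocks:
    @pytest.mark.parametrize("builder,channels,side", [
        (build_block_a, 40, 9), (build_block_b, 136, 4), (build_block_c, 4, 3),
    ])
    def test_shape_preserved(self, builder, channels, side, rng):
        cfg = ArchConfig.tiny(n_classes=12)
        g = builder(cfg, in_channels=channels)
        x = rng.standard_normal((2, side, side, channels)).astype(np.float32)
        out = g.forward(x, g.init_params(0), g.init_state())["output"]
        assert out.data.shape == x.shape

    def test_zeroed_branches_reduce_to_identity_then_relu(self, rng):
        """With the projection weights and bias zeroed the block is
        x -> ReLU(x + scale*0) = ReLU(x)."""
        cfg = ArchConfig.tiny(n_classes=12)
        g = build_block_a(cfg, in_channels=8)
        params = g.init_params(0)
        params["block_a_up.w"][:] = 0.0
        params["block_a_up.b"][:] = 0.0
        x = rng.standard_normal((1, 7, 7, 8)).astype(np.float32)
        out = g.forward(x, params, g.init_state())["output"]
        np.testing.assert_array_equal(out.data, np.maximum(x, 0.0))

    def test_zero_input_zero_projection_gives_zero_map(self):
        cfg = ArchConfig.tiny(n_classes=12)
        g = build_block_a(cfg, in_channels=8)
        params = g.init_params(0)
        params["block_a_up.w"][:] = 0.0
        params["block_a_up.b"][:] = 0.0
        x = np.zeros((1, 5, 5, 8), np.float32)
        out = g.forward(x, params, g.init_state())["output"]
        np.testing.assert_array_equal(out.data, 0.0)

    def test_block_a_matches_straight_line_oracle(self, rng):
        """Eval-mode forward of the A block agrees with an equation-by-
        equation transcription (branch convs, concat, projection, scaled
        residual add, ReLU) built on sliding-window einsum convolutions."""
        from test_ops import conv_oracle

        cfg = ArchConfig(n_classes=107)
        g = build_block_a(cfg)  # 320-channel reference block
        params = g.init_params(3)
        state = g.init_state()
        x = rng.standard_normal((1, 7, 7, 320)).astype(np.float32)
        got = g.forward(x, params, state)["output"].data

        def cbr(v, name, padding):
            v = conv_oracle(v, params[f"{name}_conv.w"], padding=padding)
            v = (v - state[f"{name}_bn.mean"]) / np.sqrt(
                state[f"{name}_bn.var"] + 1e-3) + params[f"{name}_bn.beta"]
            return np.maximum(v, 0.0)

        b0 = cbr(x, "block_a_b0l0", "valid")
        b1 = cbr(cbr(x, "block_a_b1l0", "valid"), "block_a_b1l1", "same")
        b2 = cbr(cbr(cbr(x, "block_a_b2l0", "valid"), "block_a_b2l1", "same"),
                 "block_a_b2l2", "same")
        cat = np.concatenate([b0, b1, b2], axis=-1)
        up = conv_oracle(cat, params["block_a_up.w"]) + params["block_a_up.b"]
        want = np.maximum(x + 0.17 * up, 0.0)
        np.testing.assert_allclose(got, want, rtol=1e-4, atol=1e-4)


class TestReductions:
    @pytest.mark.parametrize("side,expected", [(35, 17), (17, 8), (3, 1)])
    def test_spatial_contraction(self, side, expected):
        cfg = ArchConfig.tiny(n_classes=12)
        g = build_reduction_a(cfg, in_channels=8)
        out_shape = g.infer_shapes((side, side, 8))[g.output]
        assert out_shape[:2] == (expected, expected)
        assert out_shape == (expected, expected, 8 + 2 * cfg.width(384))

    def test_forward_shape_agrees_with_propagation(self, rng):
        cfg = ArchConfig.tiny(n_classes=12)
        for builder, cin in ((build_reduction_a, 8), (build_reduction_b, 16)):
            g = builder(cfg, in_channels=cin)
            x = rng.standard_normal((1, 9, 9, cin)).astype(np.float32)
            out = g.forward(x, g.init_params(0), g.init_state())["output"]
            assert out.data.shape[1:] == g.infer_shapes((9, 9, cin))[g.output]


class TestBackbone:
    def test_reference_final_map_is_8x8x1536(self):
        g = build_backbone(REFERENCE)
        assert g.infer_shapes((299, 299, 3))[g.taps["backbone"]] == (8, 8, 1536)

    def test_reference_parameter_count(self):
        assert count_parameters(build_backbone(REFERENCE)) == 54_336_736

    def test_count_matches_independent_stage_enumeration(self):
        assert count_parameters(build_backbone(REFERENCE)) == (
            CONV_WEIGHTS + PROJECTION_BIASES + 3 * BN_CHANNELS)

    @pytest.mark.parametrize("cfg", [
        ArchConfig.tiny(n_classes=12),
        ArchConfig(n_classes=10, dialect="original", input_size=96,
                   width_multiplier=0.125),
        ArchConfig(n_classes=10, input_size=96, width_multiplier=0.25,
                   repeats_a=2, repeats_b=2, repeats_c=2),
    ])
    def test_count_matches_instantiated_arrays(self, cfg):
        """Closed-form counting equals the brute-force sum over the
        actually allocated parameter arrays plus running statistics."""
        g = build_backbone(cfg)
        params = g.init_params(0)
        state = g.init_state()
        brute = sum(a.size for a in params.values())
        brute += sum(a.size for a in state.values())
        assert g.param_count() == brute

    def test_batchnorm_counts_shift_plus_running_stats(self):
        """A batch norm over C channels contributes 3C: one shift plus the
        running mean and variance (scale-free normalization)."""
        g = ModelGraph()
        g.add("input", "input")
        g.add("norm", "bn", "input", channels=32)
        assert g.param_count() == 96

    def test_original_dialect_repeats_and_output(self):
        cfg = ArchConfig(n_classes=10, dialect="original")
        assert (cfg.repeats_a, cfg.repeats_b, cfg.repeats_c) == (5, 10, 5)
        g = build_backbone(cfg)
        assert g.infer_shapes((299, 299, 3))[g.taps["backbone"]] == (8, 8, 2080)

    def test_tiny_forward_matches_shape_propagation(self, rng, tiny_arch):
        g = build_backbone(tiny_arch)
        x = rng.standard_normal((1, 96, 96, 3)).astype(np.float32)
        out = g.forward(x, g.init_params(0), g.init_state())["output"]
        assert out.data.shape[1:] == g.infer_shapes((96, 96, 3))[g.output]
        assert out.data.shape[-1] == backbone_channels(tiny_arch)

    def test_forward_is_deterministic(self, rng, tiny_arch):
        g = build_backbone(tiny_arch)
        params, state = g.init_params(0), g.init_state()
        x = rng.standard_normal((1, 96, 96, 3)).astype(np.float32)
        a = g.forward(x, params, state)["output"].data
        b = g.forward(x, params, state)["output"].data
        np.testing.assert_array_equal(a, b)

    def test_channel_mismatch_raises(self):
        g = build_backbone(REFERENCE)
        with pytest.raises(GraphError, match="channels"):
            g.infer_shapes((299, 299, 4))


class TestArchConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ArchConfig(n_classes=1)
        with pytest.raises(ValueError):
            ArchConfig(n_classes=5, dropout_rate=1.0)
        with pytest.raises(ValueError):
            ArchConfig(n_classes=5, dialect="bogus")
        with pytest.raises(ValueError):
            ArchConfig(n_classes=5, residual_scales=(0.0, 0.1, 0.2))

    def test_width_multiplier_keeps_branches_nonempty(self):
        cfg = ArchConfig(n_classes=5, width_multiplier=0.01)
        assert cfg.width(32) == 1
        assert cfg.width(1536) == 15
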