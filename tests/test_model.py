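"""Model operations against brute-force oracles, plus shape/determinism
contracts."""

import numpy as np
import pytest

from eegmixer import ConvMixerECA, ModelConfig, eca_kernel_size
from eegmixer.autodiff import Tensor
from eegmixer.errors import ConfigError
from eegmixer.model import (
    depthwise_conv,
    eca_block,
    mixer_block,
    patch_embed,
    pointwise_conv,
)


# ------------------------------------------------------- brute-force oracles
def depthwise_oracle(x, w, b=None):
    B, C, L = x.shape
    K = w.shape[-1]
    pad = K // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    out = np.zeros_like(x)
    for bi in range(B):
        for c in range(C):
            for pos in range(L):
                out[bi, c, pos] = np.dot(xp[bi, c, pos : pos + K], w[c, 0])
                if b is not None:
                    out[bi, c, pos] += b[c]
    return out


def pointwise_oracle(x, w, b=None):
    B, C_in, L = x.shape
    C_out = w.shape[0]
    out = np.zeros((B, C_out, L))
    for bi in range(B):
        for pos in range(L):
            out[bi, :, pos] = w[:, :, 0] @ x[bi, :, pos]
            if b is not None:
                out[bi, :, pos] += b
    return out


def eca_circular_oracle(z, w):
    """Symmetric circular channel convolution via an explicit modular loop."""
    B, C = z.shape
    K = len(w)
    out = np.zeros_like(z)
    for bi in range(B):
        for c in range(C):
            for i in range(K):
                out[bi, c] += w[i] * z[bi, (c + i - K // 2) % C]
    return out


# --------------------------------------------------------------- kernel rule
class TestEcaKernelSize:
    @pytest.mark.parametrize(
        "channels,gamma,rule,expected",
        [
            (2, 2.0, "linear", 3),     # round(1)+1 = 2, bumped to odd 3
            (64, 32.0, "linear", 3),   # round(2)+1 = 3
            (64, 2.0, "linear", 33),   # round(32)+1 = 33
            (64, 2.0, "eca-log2", 3),      # |6/2 + 1/2| = 3.5 -> 3
            (256, 2.0, "eca-log2", 5),     # |8/2 + 1/2| = 4.5 -> 5
            (1, 2.0, "eca-log2", 3),       # floor at 3
        ],
    )
    def test_rules_match_hand_computation(self, channels, gamma, rule, expected):
        assert eca_kernel_size(channels, gamma, rule) == expected

    def test_result_is_always_odd_and_at_least_3(self):
        for c in range(1, 130):
            for rule in ("linear", "eca-log2"):
                k = eca_kernel_size(c, 2.0, rule)
                assert k % 2 == 1 and k >= 3

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigError):
            eca_kernel_size(0, 2.0)
        with pytest.raises(ConfigError):
            eca_kernel_size(8, -1.0)


# ------------------------------------------------------------- primitive ops
class TestPatchEmbed:
    def test_output_shape_follows_floor_rule(self, rng):
        w = Tensor(rng.standard_normal((64, 19, 4)))
        b = Tensor(np.zeros(64))
        out = patch_embed(rng.standard_normal((2, 19, 512)), w, b, 4)
        assert out.shape == (2, 64, 128)

    def test_identity_kernel_with_patch_one_reproduces_channels(self, rng):
        c = 3
        w = np.zeros((c, c, 1))
        w[np.arange(c), np.arange(c), 0] = 1.0
        x = rng.standard_normal((2, c, 16))
        out = patch_embed(x, Tensor(w), Tensor(np.zeros(c)), 1)
        np.testing.assert_allclose(out.data, x)

    def test_zero_input_zero_bias_gives_zero_tokens(self, rng):
        w = Tensor(rng.standard_normal((8, 3, 4)))
        out = patch_embed(np.zeros((1, 3, 16)), w, Tensor(np.zeros(8)), 4)
        np.testing.assert_allclose(out.data, 0.0)

    def test_input_shorter_than_patch_rejected(self, rng):
        w = Tensor(rng.standard_normal((8, 3, 4)))
        with pytest.raises(ConfigError):
            patch_embed(np.zeros((1, 3, 2)), w, Tensor(np.zeros(8)), 4)


class TestDepthwiseConv:
    def test_centered_delta_kernel_is_identity(self, rng):
        c = 4
        w = np.zeros((c, 1, 3))
        w[:, 0, 1] = 1.0
        x = rng.standard_normal((2, c, 10))
        out = depthwise_conv(x, Tensor(w))
        np.testing.assert_allclose(out.data, x)

    def test_matches_sliding_window_oracle(self, rng):
        x = rng.standard_normal((2, 3, 8))
        w = rng.standard_normal((3, 1, 3))
        b = rng.standard_normal(3)
        out = depthwise_conv(x, Tensor(w), Tensor(b))
        np.testing.assert_allclose(out.data, depthwise_oracle(x, w, b), rtol=1e-10)

    def test_channels_do_not_mix(self, rng):
        x = rng.standard_normal((1, 3, 8))
        w = Tensor(rng.standard_normal((3, 1, 3)))
        base = depthwise_conv(x, w).data
        x2 = x.copy()
        x2[0, 1] += 1.0
        perturbed = depthwise_conv(x2, w).data
        np.testing.assert_allclose(perturbed[0, [0, 2]], base[0, [0, 2]])
        assert not np.allclose(perturbed[0, 1], base[0, 1])

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ConfigError):
            depthwise_conv(np.zeros((1, 2, 8)), Tensor(np.zeros((2, 1, 4))))


class TestPointwiseConv:
    def test_identity_weight_is_identity(self, rng):
        c = 4
        w = np.eye(c)[:, :, None]
        x = rng.standard_normal((2, c, 5))
        np.testing.assert_allclose(pointwise_conv(x, Tensor(w)).data, x)

    def test_matches_per_position_matmul_oracle(self, rng):
        x = rng.standard_normal((2, 4, 5))
        w = rng.standard_normal((4, 4, 1))
        b = rng.standard_normal(4)
        out = pointwise_conv(x, Tensor(w), Tensor(b))
        np.testing.assert_allclose(out.data, pointwise_oracle(x, w, b), rtol=1e-10)

    def test_commutes_with_position_permutation(self, rng):
        x = rng.standard_normal((1, 3, 6))
        w = Tensor(rng.standard_normal((3, 3, 1)))
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            pointwise_conv(x[:, :, perm], w).data,
            pointwise_conv(x, w).data[:, :, perm],
        )

    def test_wide_kernel_rejected(self, rng):
        with pytest.raises(ConfigError):
            pointwise_conv(np.zeros((1, 3, 6)), Tensor(np.zeros((3, 3, 2))))


class TestEcaBlock:
    def test_channel_constant_input_gives_equal_weights(self, rng):
        x = np.tile(rng.standard_normal((1, 1, 10)), (1, 5, 1))
        _, a = eca_block(x, Tensor(rng.standard_normal((1, 1, 3))))
        np.testing.assert_allclose(a.data, np.full_like(a.data, a.data[0, 0]), rtol=1e-12)

    def test_attention_weights_strictly_in_unit_interval(self, rng):
        x = rng.standard_normal((3, 8, 10)) * 10
        _, a = eca_block(x, Tensor(rng.standard_normal((1, 1, 3)) * 5))
        assert np.all(a.data > 0) and np.all(a.data < 1)

    def test_output_magnitude_never_exceeds_input(self, rng):
        x = rng.standard_normal((2, 6, 12))
        out, _ = eca_block(x, Tensor(rng.standard_normal((1, 1, 3))))
        assert np.all(np.abs(out.data) <= np.abs(x) + 1e-12)

    def test_circular_convolution_matches_modular_index_oracle(self, rng):
        c, k = 5, 3
        x = rng.standard_normal((2, c, 7))
        w = rng.standard_normal(k)
        out, a = eca_block(x, Tensor(w.reshape(1, 1, k)))
        z = x.mean(axis=2)
        expected_gates = 1.0 / (1.0 + np.exp(-eca_circular_oracle(z, w)))
        np.testing.assert_allclose(a.data, expected_gates, rtol=1e-10)
        np.testing.assert_allclose(out.data, x * expected_gates[:, :, None], rtol=1e-10)

    def test_kernel_wider_than_channel_wrap_rejected(self, rng):
        with pytest.raises(ConfigError):
            eca_block(np.zeros((1, 2, 4)), Tensor(np.zeros((1, 1, 5))))


class TestMixerBlock:
    def _params(self, cfg, rng, zero=False):
        model = ConvMixerECA(cfg, seed=0)
        p = model._block_params(0)
        if zero:
            for k in ("dw_weight", "dw_bias", "pw_weight", "pw_bias"):
                p[k] = Tensor(np.zeros_like(p[k].data))
        return p

    def test_zeroed_block_reduces_to_residual_identity(self, rng):
        cfg = ModelConfig(in_channels=3, hidden_dim=6, depth=1, dw_kernel=3)
        p = self._params(cfg, rng, zero=True)
        x = rng.standard_normal((2, 6, 8))
        out, _ = mixer_block(x, p, cfg)
        np.testing.assert_allclose(out.data, x)  # GELU(0)=0, gates scale zeros

    def test_shape_preserved_for_random_configs(self, rng):
        for hidden in (4, 8):
            cfg = ModelConfig(in_channels=3, hidden_dim=hidden, depth=1, dw_kernel=3)
            p = self._params(cfg, rng)
            x = rng.standard_normal((2, hidden, 11))
            out, _ = mixer_block(x, p, cfg)
            assert out.shape == x.shape

    def test_saturated_gates_recover_attention_free_block(self, rng):
        cfg_eca = ModelConfig(in_channels=3, hidden_dim=4, depth=1, dw_kernel=3)
        cfg_none = ModelConfig(in_channels=3, hidden_dim=4, depth=1, dw_kernel=3,
                               attention="none")
        # identity convs on a positive input keep the pooled descriptor
        # positive, so a huge kernel saturates every sigmoid gate to 1
        dw = np.zeros((4, 1, 3))
        dw[:, 0, 1] = 1.0
        p = {
            "dw_weight": Tensor(dw),
            "dw_bias": Tensor(np.zeros(4)),
            "pw_weight": Tensor(np.eye(4)[:, :, None]),
            "pw_bias": Tensor(np.zeros(4)),
            "eca_weight": Tensor(np.full((1, 1, 3), 1e4)),
        }
        x = np.abs(rng.standard_normal((2, 4, 8))) + 1.0
        out_eca, gates = mixer_block(x, p, cfg_eca)
        assert np.all(gates.data > 1 - 1e-12)
        p_none = {k: v for k, v in p.items() if k != "eca_weight"}
        out_none, _ = mixer_block(x, p_none, cfg_none)
        np.testing.assert_allclose(out_eca.data, out_none.data, rtol=1e-8)


# ------------------------------------------------------------------- forward
class TestForward:
    def test_default_architecture_logit_shape(self, rng):
        model = ConvMixerECA(ModelConfig(), seed=0)
        logits = model.forward(rng.standard_normal((2, 19, 512)))
        assert logits.shape == (2, 1)

    def test_softmax_head_emits_n_class_logits(self, rng):
        model = ConvMixerECA(ModelConfig(head="n-class-softmax"), seed=0)
        logits = model.forward(rng.standard_normal((2, 19, 512)))
        assert logits.shape == (2, 2)

    def test_gap_of_position_constant_tokens_returns_the_constant(self, rng):
        v = rng.standard_normal((2, 5))
        tokens = Tensor(np.repeat(v[:, :, None], 7, axis=2))
        np.testing.assert_allclose(tokens.mean(axis=2).data, v)

    def test_duplicated_sample_duplicates_its_logit(self, tiny_model, rng):
        x = rng.standard_normal((2, 3, 16))
        batch = np.concatenate([x, x[:1]], axis=0)
        logits = tiny_model.forward(batch)
        np.testing.assert_array_equal(logits[0], logits[2])

    def test_trace_captures_embedding_and_every_block(self, tiny_model, rng):
        x = rng.standard_normal((3, 3, 16))
        logits, trace = tiny_model.forward(x, trace=True)
        assert len(trace.activations) == tiny_model.config.depth + 1
        shapes = {a.shape for a in trace.activations}
        assert shapes == {(3, 8, 4)}  # blocks are shape-preserving
        np.testing.assert_array_equal(trace.logits, logits)

    def test_wrong_channel_count_rejected(self, tiny_model, rng):
        with pytest.raises(ConfigError):
            tiny_model.forward(rng.standard_normal((1, 5, 16)))


class TestDeterminismAndParameters:
    def test_same_seed_gives_bitwise_identical_initialization(self):
        a = ConvMixerECA(ModelConfig(), seed=42)
        b = ConvMixerECA(ModelConfig(), seed=42)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k].data, b.params[k].data)

    def test_different_seed_changes_initialization(self):
        a = ConvMixerECA(ModelConfig(), seed=1)
        b = ConvMixerECA(ModelConfig(), seed=2)
        assert any(
            not np.array_equal(a.params[k].data, b.params[k].data) for k in a.params
        )

    def test_parameter_count_is_independent_of_input_length(self, rng):
        model = ConvMixerECA(ModelConfig(), seed=0)
        n0 = model.n_parameters()
        model.forward(rng.standard_normal((1, 19, 512)))
        model.forward(rng.standard_normal((1, 19, 256)))
        assert model.n_parameters() == n0
        assert n0 == ConvMixerECA(ModelConfig(), seed=5).n_parameters()

    def test_checkpoint_round_trip_preserves_parameters(self, tiny_model, tmp_path, rng):
        path = tmp_path / "ckpt.h5"
        tiny_model.save(path)
        restored = ConvMixerECA.load(path)
        assert restored.config == tiny_model.config
        x = rng.standard_normal((2, 3, 16))
        np.testing.assert_array_equal(restored.forward(x), tiny_model.forward(x))
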