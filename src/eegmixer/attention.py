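"""Alternative channel-attention blocks for the mixer: squeeze-and-excite
(SEA), convolutional block attention (CBA), and non-local attention (NLA).

All three are drop-in replacements for the ECA stage: they take a
[B x C x L] tensor and return one of the same shape.  The formulations
follow the canonical literature definitions adapted to 1-D sequences:

* SEA — global average pool, bottleneck MLP (reduction r), sigmoid gates.
* CBA — CBAM-style: channel attention from shared-MLP(avg-pool) +
  shared-MLP(max-pool), then spatial attention from a convolution over the
  stacked channel-avg and channel-max maps.
* NLA — embedded-Gaussian non-local block over positions with a residual;
  the position-to-position attention matrix is row-stochastic.
"""

from __future__ import annotations

from .autodiff import Tensor, cat


def sea_block(x: Tensor, params: dict[str, Tensor]) -> tuple[Tensor, Tensor]:
    """Squeeze-and-excitation channel gating; returns ``(gated, gates)``."""
    b, c, _ = x.shape
    z = x.mean(axis=2)                                    # [B x C]
    h = (z @ params["sea_w1"].transpose() + params["sea_b1"]).relu()
    gates = (h @ params["sea_w2"].transpose() + params["sea_b2"]).sigmoid()
    return x * gates.reshape(b, c, 1), gates


def cba_block(x: Tensor, params: dict[str, Tensor]) -> tuple[Tensor, Tensor]:
    """CBAM-style channel-then-spatial attention; returns ``(out, channel_gates)``."""
    b, c, length = x.shape
    w1_t = params["cba_w1"].transpose()
    w2_t = params["cba_w2"].transpose()
    avg = x.mean(axis=2)                                  # [B x C]
    mx = x.max(axis=2)
    ch_logits = (avg @ w1_t).relu() @ w2_t + (mx @ w1_t).relu() @ w2_t
    ch_gates = ch_logits.sigmoid()                        # [B x C]
    h = x * ch_gates.reshape(b, c, 1)
    sp_avg = h.mean(axis=1, keepdims=True)                # [B x 1 x L]
    sp_max = h.max(axis=1, keepdims=True)
    sp_in = cat([sp_avg, sp_max], axis=1)                 # [B x 2 x L]
    k = params["cba_spatial"].shape[-1]
    sp_gates = sp_in.conv1d(params["cba_spatial"], padding=k // 2).sigmoid()
    return h * sp_gates, ch_gates


def nla_block(x: Tensor, params: dict[str, Tensor]) -> Tensor:
    """Embedded-Gaussian non-local block over positions with residual."""
    theta = x.conv1d(params["nla_theta"])                 # [B x d x L]
    phi = x.conv1d(params["nla_phi"])
    g = x.conv1d(params["nla_g"])
    logits = theta.transpose(0, 2, 1) @ phi               # [B x L x L]
    attn = logits.softmax(axis=-1)                        # rows sum to 1
    mixed = g @ attn.transpose(0, 2, 1)                   # [B x d x L]
    return x + mixed.conv1d(params["nla_out"])


def nla_attention_matrix(x: Tensor, params: dict[str, Tensor]) -> Tensor:
    """The row-stochastic position attention matrix, exposed for inspection."""
    theta = x.conv1d(params["nla_theta"])
    phi = x.conv1d(params["nla_phi"])
    return (theta.transpose(0, 2, 1) @ phi).softmax(axis=-1)
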