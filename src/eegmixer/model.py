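"""The ConvMixer-ECA network for 1-D multichannel EEG epochs.

The architecture tokenizes a [channels x time] epoch with a strided 1-D
convolution (patch embedding), then stacks ``depth`` shape-preserving mixer
blocks.  Each block applies a depthwise convolution (temporal mixing within
each hidden channel), GELU, a pointwise convolution (cross-channel mixing),
and a channel-attention stage, with a residual connection wrapping the
whole block:

    X' = X + Attn(PW(GELU(DW(X))))

The default attention stage is efficient channel attention (ECA): global
average pooling over positions gives a per-channel descriptor, a small 1-D
convolution slides across the *channel* axis (circular indexing), and a
sigmoid produces multiplicative channel gates.  The head is global average
pooling over positions, layer normalization, and an affine classifier.

Everything is written against the package's own autodiff engine
(:mod:`eegmixer.autodiff`), so the same functions serve inference and
gradient-based training.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import Tensor, cat
from .errors import ConfigError

__all__ = [
    "ModelConfig",
    "ForwardTrace",
    "ConvMixerECA",
    "eca_kernel_size",
    "patch_embed",
    "depthwise_conv",
    "pointwise_conv",
    "eca_block",
    "mixer_block",
    "layer_norm",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Only the depth (8) is fixed by the method description; patch size,
    hidden dimension, and depthwise kernel default to the original
    ConvMixer choices scaled to 1-D EEG epochs.
    """

    in_channels: int = 19
    n_classes: int = 2
    patch_size: int = 4
    hidden_dim: int = 64
    depth: int = 8
    dw_kernel: int = 9
    eca_gamma: float = 2.0
    eca_rule: str = "eca-log2"          # or "linear"
    eca_padding: str = "circular"       # or "zero"
    attention: str = "eca"              # none | eca | sea | cba | nla
    head: str = "single-logit-sigmoid"  # or "n-class-softmax"
    residual: str = "block"             # "block" or "depthwise" (original ConvMixer)
    sea_reduction: int = 16
    nla_embed_dim: int | None = None
    cba_spatial_kernel: int = 7

    def __post_init__(self):
        if self.patch_size < 1:
            raise ConfigError(f"patch_size must be >= 1, got {self.patch_size}")
        if self.dw_kernel % 2 == 0:
            raise ConfigError(f"depthwise kernel must be odd, got {self.dw_kernel}")
        if self.eca_gamma <= 0:
            raise ConfigError(f"eca_gamma must be positive, got {self.eca_gamma}")
        if self.attention not in ("none", "eca", "sea", "cba", "nla"):
            raise ConfigError(f"unknown attention kind {self.attention!r}")
        if self.head not in ("single-logit-sigmoid", "n-class-softmax"):
            raise ConfigError(f"unknown head {self.head!r}")
        if self.residual not in ("block", "depthwise"):
            raise ConfigError(f"unknown residual placement {self.residual!r}")
        if self.eca_rule not in ("eca-log2", "linear"):
            raise ConfigError(f"unknown ECA kernel rule {self.eca_rule!r}")
        if self.cba_spatial_kernel % 2 == 0:
            raise ConfigError("cba_spatial_kernel must be odd")

    @property
    def n_out(self) -> int:
        return 1 if self.head == "single-logit-sigmoid" else self.n_classes

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class ForwardTrace:
    """Per-layer activations captured during a traced forward pass."""

    activations: list[np.ndarray] = field(default_factory=list)  # embed + each block
    pooled: np.ndarray | None = None      # [B x C_p] after GAP
    logits: np.ndarray | None = None      # [B x n_out]
    attention: list[np.ndarray] = field(default_factory=list)    # per-block channel gates

    @property
    def layer_names(self) -> list[str]:
        return ["embed"] + [f"block{i}" for i in range(len(self.activations) - 1)]


def eca_kernel_size(channels: int, gamma: float = 2.0, rule: str = "eca-log2") -> int:
    """Adaptive ECA kernel size from the channel count.

    ``eca-log2`` follows the original ECA recipe
    ``k = |log2(C)/gamma + 1/gamma|`` truncated to an integer and bumped to
    odd; ``linear`` uses the linear rule ``k = round(C/gamma) + 1``
    (round half away from zero).  Either result is raised to the nearest
    odd integer >= 3 so the circular neighborhood stays symmetric.
    """
    if channels < 1:
        raise ConfigError(f"channels must be >= 1, got {channels}")
    if gamma <= 0:
        raise ConfigError(f"gamma must be positive, got {gamma}")
    if rule == "linear":
        k = int(math.floor(channels / gamma + 0.5)) + 1
    elif rule == "eca-log2":
        t = abs(math.log2(channels) / gamma + 1.0 / gamma)
        k = int(t)
        if k % 2 == 0:
            k += 1
    else:
        raise ConfigError(f"unknown ECA kernel rule {rule!r}")
    if k % 2 == 0:
        k += 1
    return max(k, 3)


# ------------------------------------------------------------- primitive ops
def patch_embed(x: Tensor | np.ndarray, weight: Tensor, bias: Tensor,
                patch_size: int) -> Tensor:
    """Tokenize [B x C_in x L] into [B x C_p x floor(L/p)] via a strided conv."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    if x.shape[-1] < patch_size:
        raise ConfigError(
            f"input length {x.shape[-1]} shorter than patch size {patch_size}"
        )
    return x.conv1d(weight, bias, stride=patch_size)


def depthwise_conv(x: Tensor | np.ndarray, weight: Tensor,
                   bias: Tensor | None = None) -> Tensor:
    """Per-channel temporal convolution with same-padding; no channel mixing."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    k = weight.shape[-1]
    if k % 2 == 0:
        raise ConfigError(f"depthwise kernel must be odd, got {k}")
    c = x.shape[1]
    return x.conv1d(weight, bias, stride=1, padding=k // 2, groups=c)


def pointwise_conv(x: Tensor | np.ndarray, weight: Tensor,
                   bias: Tensor | None = None) -> Tensor:
    """Position-wise linear map across channels (1x1 convolution)."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    if weight.shape[-1] != 1:
        raise ConfigError(f"pointwise kernel must have width 1, got {weight.shape}")
    return x.conv1d(weight, bias, stride=1)


def eca_block(x: Tensor | np.ndarray, weight: Tensor, *,
              padding: str = "circular") -> tuple[Tensor, Tensor]:
    """Efficient channel attention.

    ``x`` is [B x C x L]; ``weight`` is the [1 x 1 x k] channel-axis kernel.
    Pools positions to a channel descriptor z, convolves z across the
    channel axis (circular indexing by default, zero-padding optionally),
    gates with a sigmoid, and rescales the input.  Returns
    ``(gated_x, attention_weights [B x C])``.
    """
    x = x if isinstance(x, Tensor) else Tensor(x)
    b, c, _ = x.shape
    k = weight.shape[-1]
    if k % 2 == 0:
        raise ConfigError(f"ECA kernel must be odd, got {k}")
    if k > 2 * c - 1:
        raise ConfigError(f"ECA kernel {k} too wide for {c} channels")
    z = x.mean(axis=2)                      # [B x C]
    z = z.reshape(b, 1, c)                  # channel axis becomes the conv axis
    if padding == "circular":
        z = z.pad_circular(k // 2, axis=-1)
        zhat = z.conv1d(weight)
    elif padding == "zero":
        zhat = z.conv1d(weight, padding=k // 2)
    else:
        raise ConfigError(f"unknown ECA padding {padding!r}")
    a = zhat.reshape(b, c).sigmoid()        # [B x C], strictly in (0, 1)
    gated = x * a.reshape(b, c, 1)
    return gated, a


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered**2.0).mean(axis=-1, keepdims=True)
    return centered * (var + eps) ** -0.5 * gain + bias


def mixer_block(x: Tensor | np.ndarray, block_params: dict[str, Tensor],
                config: ModelConfig) -> tuple[Tensor, Tensor | None]:
    """One ConvMixer block; returns ``(output, channel_attention | None)``."""
    from . import attention as attn  # local import to avoid a cycle

    x = x if isinstance(x, Tensor) else Tensor(x)
    h = depthwise_conv(x, block_params["dw_weight"], block_params["dw_bias"])
    if config.residual == "depthwise":  # original ConvMixer placement
        h = h.gelu() + x
        inner = pointwise_conv(h, block_params["pw_weight"], block_params["pw_bias"])
    else:
        inner = pointwise_conv(h.gelu(), block_params["pw_weight"], block_params["pw_bias"])
    gates: Tensor | None = None
    if config.attention == "eca":
        inner, gates = eca_block(inner, block_params["eca_weight"],
                                 padding=config.eca_padding)
    elif config.attention == "sea":
        inner, gates = attn.sea_block(inner, block_params)
    elif config.attention == "cba":
        inner, gates = attn.cba_block(inner, block_params)
    elif config.attention == "nla":
        inner = attn.nla_block(inner, block_params)
    if config.residual == "depthwise":
        out = inner
    else:
        out = x + inner
    return out, gates


# ---------------------------------------------------------------- the model
class ConvMixerECA:
    """ConvMixer with channel attention for EEG epoch classification.

    Parameters are plain named tensors in :attr:`params`; convolution
    weights use uniform fan-in initialization from a fixed seed (bitwise
    reproducible) and the classification head starts at zero, so an
    untrained model predicts the uninformative prior.
    """

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        self.seed = seed
        self.params: dict[str, Tensor] = self._init_params(np.random.default_rng(seed))

    # ------------------------------------------------------------------ init
    def _uniform(self, rng: np.random.Generator, shape: tuple[int, ...],
                 fan_in: int) -> np.ndarray:
        bound = 1.0 / math.sqrt(fan_in)
        return rng.uniform(-bound, bound, size=shape)

    def _init_params(self, rng: np.random.Generator) -> dict[str, Tensor]:
        cfg = self.config
        c_in, c_p, p = cfg.in_channels, cfg.hidden_dim, cfg.patch_size
        params: dict[str, np.ndarray] = {}
        params["embed_weight"] = self._uniform(rng, (c_p, c_in, p), c_in * p)
        params["embed_bias"] = self._uniform(rng, (c_p,), c_in * p)
        k_eca = eca_kernel_size(c_p, cfg.eca_gamma, cfg.eca_rule)
        for i in range(cfg.depth):
            pre = f"block{i}."
            params[pre + "dw_weight"] = self._uniform(
                rng, (c_p, 1, cfg.dw_kernel), cfg.dw_kernel
            )
            params[pre + "dw_bias"] = self._uniform(rng, (c_p,), cfg.dw_kernel)
            params[pre + "pw_weight"] = self._uniform(rng, (c_p, c_p, 1), c_p)
            params[pre + "pw_bias"] = self._uniform(rng, (c_p,), c_p)
            if cfg.attention == "eca":
                params[pre + "eca_weight"] = self._uniform(rng, (1, 1, k_eca), k_eca)
            elif cfg.attention == "sea":
                r = max(1, min(cfg.sea_reduction, c_p))
                c_mid = max(1, c_p // r)
                params[pre + "sea_w1"] = self._uniform(rng, (c_mid, c_p), c_p)
                params[pre + "sea_b1"] = np.zeros(c_mid)
                params[pre + "sea_w2"] = self._uniform(rng, (c_p, c_mid), c_mid)
                params[pre + "sea_b2"] = np.zeros(c_p)
            elif cfg.attention == "cba":
                r = max(1, min(cfg.sea_reduction, c_p))
                c_mid = max(1, c_p // r)
                params[pre + "cba_w1"] = self._uniform(rng, (c_mid, c_p), c_p)
                params[pre + "cba_w2"] = self._uniform(rng, (c_p, c_mid), c_mid)
                params[pre + "cba_spatial"] = self._uniform(
                    rng, (1, 2, cfg.cba_spatial_kernel), 2 * cfg.cba_spatial_kernel
                )
            elif cfg.attention == "nla":
                d = cfg.nla_embed_dim or max(1, c_p // 2)
                params[pre + "nla_theta"] = self._uniform(rng, (d, c_p, 1), c_p)
                params[pre + "nla_phi"] = self._uniform(rng, (d, c_p, 1), c_p)
                params[pre + "nla_g"] = self._uniform(rng, (d, c_p, 1), c_p)
                params[pre + "nla_out"] = self._uniform(rng, (c_p, d, 1), d)
        params["ln_gain"] = np.ones(c_p)
        params["ln_bias"] = np.zeros(c_p)
        # zero-initialized head: the untrained classifier outputs zero
        # logits, so training starts exactly at the no-information BCE ln 2
        params["fc_weight"] = np.zeros((c_p, cfg.n_out))
        params["fc_bias"] = np.zeros(cfg.n_out)
        return {k: Tensor(v, requires_grad=True, name=k) for k, v in params.items()}

    # --------------------------------------------------------------- forward
    def _block_params(self, i: int) -> dict[str, Tensor]:
        pre = f"block{i}."
        return {k[len(pre):]: v for k, v in self.params.items() if k.startswith(pre)}

    def forward_tensor(self, x: Tensor | np.ndarray,
                       trace: ForwardTrace | None = None) -> Tensor:
        """Differentiable forward pass; logits as a Tensor."""
        cfg = self.config
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.ndim != 3 or x.shape[1] != cfg.in_channels:
            raise ConfigError(
                f"expected input [B x {cfg.in_channels} x L], got {x.shape}"
            )
        h = patch_embed(x, self.params["embed_weight"], self.params["embed_bias"],
                        cfg.patch_size)
        if trace is not None:
            trace.activations.append(h.data.copy())
        for i in range(cfg.depth):
            h, gates = mixer_block(h, self._block_params(i), cfg)
            if not np.all(np.isfinite(h.data)):
                raise FloatingPointError(f"non-finite activation after block {i}")
            if trace is not None:
                trace.activations.append(h.data.copy())
                if gates is not None:
                    trace.attention.append(gates.data.copy())
        y = h.mean(axis=2)  # GAP over positions -> [B x C_p]
        if trace is not None:
            trace.pooled = y.data.copy()
        y = layer_norm(y, self.params["ln_gain"], self.params["ln_bias"])
        logits = y @ self.params["fc_weight"] + self.params["fc_bias"]
        if trace is not None:
            trace.logits = logits.data.copy()
        return logits

    def forward(self, x: np.ndarray, trace: bool = False
                ) -> np.ndarray | tuple[np.ndarray, ForwardTrace]:
        """Inference forward pass; logits as an array, optionally traced."""
        tr = ForwardTrace() if trace else None
        logits = self.forward_tensor(Tensor(np.asarray(x)), tr).data
        return (logits, tr) if trace else logits

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Positive-class probability per epoch, batched deterministically."""
        x = np.asarray(x)
        out = []
        for lo in range(0, x.shape[0], batch_size):
            logits = self.forward(x[lo : lo + batch_size])
            if self.config.head == "single-logit-sigmoid":
                out.append(1.0 / (1.0 + np.exp(-logits[:, 0])))
            else:
                shifted = logits - logits.max(axis=1, keepdims=True)
                e = np.exp(shifted)
                out.append((e / e.sum(axis=1, keepdims=True))[:, 1])
        return np.concatenate(out) if out else np.empty(0)

    # ------------------------------------------------------------- utilities
    def n_parameters(self) -> int:
        return sum(int(t.data.size) for t in self.params.values())

    def parameter_arrays(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.params.items()}

    def load_parameter_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        missing = set(self.params) ^ set(arrays)
        if missing:
            raise ConfigError(f"parameter names mismatch: {sorted(missing)}")
        for k, t in self.params.items():
            if t.data.shape != arrays[k].shape:
                raise ConfigError(
                    f"shape mismatch for {k}: {t.data.shape} vs {arrays[k].shape}"
                )
            t.data = arrays[k].astype(np.float64).copy()

    def save(self, path) -> None:
        from .io import save_checkpoint

        save_checkpoint(path, self.config.to_dict(), self.params)

    @classmethod
    def load(cls, path) -> "ConvMixerECA":
        from .io import load_checkpoint

        config_dict, arrays = load_checkpoint(path)
        model = cls(ModelConfig.from_dict(config_dict))
        model.load_parameter_arrays(arrays)
        return model
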