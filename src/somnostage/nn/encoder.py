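"""Causal-convolution attention encoder with CrossNorm.

The encoder treats a time-frequency image as a sequence of T tokens of M
features.  Each layer projects the sequence to queries, keys and values with
causal 1-D convolutions (so a token's projection sees only itself and earlier
tokens), runs multi-head scaled dot-product attention, and applies a
position-wise feed-forward network; both sub-blocks use residual connections
followed by normalization.

Normalization is standard layer norm at evaluation time.  During training,
CrossNorm augmentation may precede it: feature-wise first and second moments
(mean and standard deviation per feature, taken over the token axis) are
exchanged between randomly paired instances in the batch, widening the style
distribution the encoder sees without altering label content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from somnostage.autodiff import (
    Tensor,
    causal_conv1d,
    index_select,
    relu,
    softmax,
)
from somnostage.nn.core import Dropout, LayerNorm, Linear, Module

CROSSNORM_EPS = 1e-5
#: Probability that a training-mode forward pass applies the moment exchange.
CROSSNORM_APPLY_P = 0.5


@dataclass
class EncoderConfig:
    """Hyperparameters of one encoder stack.

    model_dim
        Feature width M of the token sequence (128 for a raw spectrogram
        channel, 3*128 after channel fusion).
    n_heads
        Attention heads; must divide ``model_dim``.
    ffn_hidden
        Hidden width of the position-wise feed-forward network.
    n_layers
        Stacked encoder layers (N_s per channel, N_m after fusion).
    causal_kernel
        Odd width of the causal Q/K/V convolutions.
    crossnorm_mode
        ``"train_only_exchange"`` pairs batch instances during training and
        exchanges their feature-wise moments before layer norm; ``"off"``
        always uses plain layer norm.
    causal_qkv
        With ``False`` the Q/K/V projections are plain affine maps — the
        basic-transformer baseline used in ablations.
    """

    model_dim: int
    n_layers: int
    n_heads: int = 8
    ffn_hidden: int = 150
    dropout: float = 0.1
    causal_kernel: int = 3
    crossnorm_mode: str = "train_only_exchange"
    causal_qkv: bool = True

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError(f"n_layers must be >= 1, got {self.n_layers}")
        if self.model_dim % self.n_heads != 0:
            raise ValueError(
                f"n_heads ({self.n_heads}) must divide model_dim ({self.model_dim})"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.causal_kernel % 2 != 1:
            raise ValueError(f"causal_kernel must be odd, got {self.causal_kernel}")
        if self.crossnorm_mode not in ("train_only_exchange", "off"):
            raise ValueError(f"unknown crossnorm_mode {self.crossnorm_mode!r}")


def sinusoid_table(n_tokens: int, dim: int) -> np.ndarray:
    """Fixed sinusoidal positional-encoding table of shape (n_tokens, dim)."""
    pos = np.arange(n_tokens)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    table = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return table


class PositionalEncoding(Module):
    """Adds the fixed sinusoidal table to a (batch, T, M) sequence."""

    def __init__(self, dim: int):
        super().__init__()
        self.dim = dim
        self._cache: dict[int, np.ndarray] = {}

    def forward(self, x: Tensor) -> Tensor:
        n = x.shape[-2]
        if n not in self._cache:
            self._cache[n] = sinusoid_table(n, self.dim)
        return x + Tensor(self._cache[n])


class CausalConv1d(Module):
    """1-D convolution along the token axis with left-only zero padding."""

    def __init__(self, in_dim: int, out_dim: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError(f"kernel width must be odd, got {kernel}")
        std = 1.0 / np.sqrt(kernel * in_dim)
        self.weight = Tensor(rng.normal(0.0, std, size=(kernel, in_dim, out_dim)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return causal_conv1d(x, self.weight, self.bias)

    def set_identity(self):
        """Make the convolution the identity map (newest tap = I); test helper."""
        k, cin, cout = self.weight.data.shape
        if cin != cout:
            raise ValueError("identity kernel requires in_dim == out_dim")
        w = np.zeros((k, cin, cout))
        w[-1] = np.eye(cin)
        self.weight.data = w
        self.bias.data = np.zeros(cout)
        return self


def crossnorm(a, b, eps: float = CROSSNORM_EPS):
    """Exchange feature-wise mean/std between two equally shaped sequences.

    ``a`` and ``b`` are arrays of shape (..., n_tokens, n_features).  Moments
    are computed per feature over the token axis.  Returns ``(a', b')`` where
    ``a'`` carries ``b``'s moments and vice versa; zero spreads are stabilized
    with ``eps`` inside the square root.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    ma = a.mean(axis=-2, keepdims=True)
    mb = b.mean(axis=-2, keepdims=True)
    # eps**2 inside the root: a zero spread maps to std = eps, healthy spreads untouched
    sa = np.sqrt(a.var(axis=-2, keepdims=True) + eps**2)
    sb = np.sqrt(b.var(axis=-2, keepdims=True) + eps**2)
    a_out = (a - ma) / sa * sb + mb
    b_out = (b - mb) / sb * sa + ma
    return a_out, b_out


def _crossnorm_exchange_batch(x: Tensor, perm: np.ndarray, eps: float = CROSSNORM_EPS) -> Tensor:
    """Differentiable in-batch moment exchange: instance i takes instance perm[i]'s moments."""
    partner = index_select(x, perm, axis=0)
    mx = x.mean(axis=1, keepdims=True)
    mp = partner.mean(axis=1, keepdims=True)
    vx = ((x - mx) ** 2).mean(axis=1, keepdims=True)
    vp = ((partner - mp) ** 2).mean(axis=1, keepdims=True)
    sx = (vx + eps**2).sqrt()
    sp = (vp + eps**2).sqrt()
    return (x - mx) / sx * sp + mp


class CrossNormLayer(Module):
    """Residual-path normalization: CrossNorm-augmented layer norm.

    Evaluation mode: plain layer norm.  Training mode (``train_only_exchange``):
    with probability :data:`CROSSNORM_APPLY_P`, batch instances are randomly
    paired and their feature-wise moments exchanged before the layer norm.
    """

    def __init__(self, dim: int, mode: str):
        super().__init__()
        self.mode = mode
        self.ln = LayerNorm(dim)

    def forward(self, x: Tensor) -> Tensor:
        if self.training and self.mode == "train_only_exchange":
            if self.rng is None:
                raise RuntimeError("training-mode CrossNorm requires apply_rng() first")
            if self.rng.random() < CROSSNORM_APPLY_P:
                perm = self.rng.permutation(x.shape[0])
                x = _crossnorm_exchange_batch(x, perm)
        return self.ln(x)


class MultiHeadAttention(Module):
    """Multi-head scaled dot-product attention with causal Q/K/V projections.

    Q, K, V are three copies of the input, each passed through its own causal
    convolution (or affine map when ``causal_qkv`` is off).  The H head outputs
    are concatenated to restore ``model_dim``; there is no output projection.
    The attention weights of the latest forward pass are kept on
    ``last_attention`` for inspection.
    """

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.n_heads = cfg.n_heads
        self.head_dim = cfg.model_dim // cfg.n_heads
        if cfg.causal_qkv:
            make = lambda: CausalConv1d(cfg.model_dim, cfg.model_dim, cfg.causal_kernel, rng)
        else:
            make = lambda: Linear(cfg.model_dim, cfg.model_dim, rng)
        self.proj_q = make()
        self.proj_k = make()
        self.proj_v = make()
        self.last_attention: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        B, T, M = x.shape
        H, d = self.n_heads, self.head_dim

        def split_heads(t: Tensor) -> Tensor:
            return t.reshape(B, T, H, d).transpose(0, 2, 1, 3)  # (B, H, T, d)

        q = split_heads(self.proj_q(x))
        k = split_heads(self.proj_k(x))
        v = split_heads(self.proj_v(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d))
        attn = softmax(scores, axis=-1)
        self.last_attention = attn.data
        out = attn @ v  # (B, H, T, d)
        return out.transpose(0, 2, 1, 3).reshape(B, T, M)


class EncoderLayer(Module):
    """Attention sub-block and feed-forward sub-block, each residual + norm."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.mha = MultiHeadAttention(cfg, rng)
        self.drop1 = Dropout(cfg.dropout)
        self.norm1 = CrossNormLayer(cfg.model_dim, cfg.crossnorm_mode)
        self.ffn_in = Linear(cfg.model_dim, cfg.ffn_hidden, rng)
        self.ffn_out = Linear(cfg.ffn_hidden, cfg.model_dim, rng)
        self.drop2 = Dropout(cfg.dropout)
        self.norm2 = CrossNormLayer(cfg.model_dim, cfg.crossnorm_mode)

    def forward(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.drop1(self.mha(x)))
        f = self.ffn_out(relu(self.ffn_in(x)))
        return self.norm2(x + self.drop2(f))


class EncoderStack(Module):
    """``n_layers`` identical encoder layers applied sequentially."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.layers = [EncoderLayer(cfg, rng) for _ in range(cfg.n_layers)]

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
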