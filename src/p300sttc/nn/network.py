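"""Transformer-CNN network built on the autodiff engine.

Architecture (time samples are tokens): learnable per-channel input gains ->
linear embedding to d_model + sinusoidal positional encoding -> 4 post-norm
Transformer encoder layers whose attention logits carry an additive prior
mask -> the n x d representation treated as a one-plane image through two
valid 3x3 conv + 2x2 max-pool stages -> MLP -> 2 logits.
"""

from __future__ import annotations

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

__all__ = [
    "Linear",
    "LayerNorm",
    "MultiHeadAttention",
    "EncoderLayer",
    "STTCNetModule",
    "sinusoidal_positional_encoding",
]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape if shape is not None else (fan_in, fan_out))


def sinusoidal_positional_encoding(n: int, d: int) -> np.ndarray:
    """Standard sin/cos positional encoding, shape (n, d)."""
    pos = np.arange(n)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    pe = np.zeros((n, d))
    pe[:, 0::2] = np.sin(angle[:, 0::2])
    pe[:, 1::2] = np.cos(angle[:, 1::2])
    return pe


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Tensor(_glorot(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.W), self.b)

    def params(self):
        return [self.W, self.b]


class LayerNorm:
    def __init__(self, d: int, eps: float = 1e-5):
        self.g = Tensor(np.ones(d), requires_grad=True)
        self.b = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = ad.tmean(x, axis=-1, keepdims=True)
        xc = ad.sub(x, mu)
        var = ad.tmean(ad.mul(xc, xc), axis=-1, keepdims=True)
        inv = ad.power(ad.add(var, self.eps), -0.5)
        return ad.add(ad.mul(ad.mul(xc, inv), self.g), self.b)

    def params(self):
        return [self.g, self.b]


class MultiHeadAttention:
    """h parallel scaled dot-product heads with a shared additive logit mask."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model, self.h = d_model, n_heads
        self.d_k = d_model // n_heads
        self.Wq = Linear(d_model, d_model, rng)
        self.Wk = Linear(d_model, d_model, rng)
        self.Wv = Linear(d_model, d_model, rng)
        self.Wo = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor, B: int, n: int) -> Tensor:
        x = ad.reshape(x, (B, n, self.h, self.d_k))
        return ad.transpose(x, (0, 2, 1, 3))  # (B, h, n, d_k)

    def __call__(self, s: Tensor, mask: np.ndarray) -> Tensor:
        B, n, _ = s.shape
        q = self._split(self.Wq(s), B, n)
        k = self._split(self.Wk(s), B, n)
        v = self._split(self.Wv(s), B, n)
        scores = ad.mul(ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))), 1.0 / np.sqrt(self.d_k))
        if mask is not None:
            scores = ad.add(scores, mask)
        attn = ad.softmax(scores, axis=-1)
        out = ad.matmul(attn, v)  # (B, h, n, d_k)
        out = ad.reshape(ad.transpose(out, (0, 2, 1, 3)), (B, n, self.d_model))
        return self.Wo(out)

    def params(self):
        return self.Wq.params() + self.Wk.params() + self.Wv.params() + self.Wo.params()


class EncoderLayer:
    """Post-norm encoder layer: MHA -> add&norm -> FFN -> add&norm."""

    def __init__(self, d_model: int, n_heads: int, ffn_dim: int, dropout: float,
                 rng: np.random.Generator):
        self.mha = MultiHeadAttention(d_model, n_heads, rng)
        self.ln1 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, ffn_dim, rng)
        self.ff2 = Linear(ffn_dim, d_model, rng)
        self.ln2 = LayerNorm(d_model)
        self.p_drop = dropout

    def __call__(self, s: Tensor, mask, training: bool, rng: np.random.Generator) -> Tensor:
        a = ad.dropout(self.mha(s, mask), self.p_drop, rng, training)
        s = self.ln1(ad.add(s, a))
        f = self.ff2(ad.relu(self.ff1(s)))
        f = ad.dropout(f, self.p_drop, rng, training)
        return self.ln2(ad.add(s, f))

    def params(self):
        return (self.mha.params() + self.ln1.params() + self.ff1.params()
                + self.ff2.params() + self.ln2.params())


class STTCNetModule:
    """Full network; operates on trials shaped (batch, channels, time)."""

    def __init__(self, n_channels: int, n_times: int, d_model: int = 64,
                 n_heads: int = 4, n_layers: int = 4, ffn_dim: int = 128,
                 conv1_filters: int = 16, conv2_filters: int = 32,
                 mlp_hidden: int = 64, dropout: float = 0.1, n_classes: int = 2,
                 channel_weights_init=None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.n_channels, self.n_times = n_channels, n_times
        self.d_model, self.n_layers = d_model, n_layers
        self.p_drop = dropout
        cw = np.ones(n_channels) if channel_weights_init is None else np.asarray(
            channel_weights_init, dtype=float)
        if cw.shape != (n_channels,):
            raise ValueError("channel_weights_init must have one weight per channel")
        self.channel_w = Tensor(cw.copy(), requires_grad=True)
        self.embed = Linear(n_channels, d_model, rng)
        self.pe = sinusoidal_positional_encoding(n_times, d_model)
        self.layers = [EncoderLayer(d_model, n_heads, ffn_dim, dropout, rng)
                       for _ in range(n_layers)]
        # CNN head geometry (valid conv 3x3, pool 2x2, twice)
        h, w = n_times, d_model
        for _ in range(2):
            h, w = (h - 2) // 2, (w - 2) // 2
            if h < 1 or w < 1:
                raise ValueError("n_times/d_model too small for the CNN head")
        self.conv1_w = Tensor(_glorot(rng, 9, conv1_filters * 9,
                                      shape=(conv1_filters, 1, 3, 3)), requires_grad=True)
        self.conv1_b = Tensor(np.zeros(conv1_filters), requires_grad=True)
        self.conv2_w = Tensor(_glorot(rng, conv1_filters * 9, conv2_filters * 9,
                                      shape=(conv2_filters, conv1_filters, 3, 3)),
                              requires_grad=True)
        self.conv2_b = Tensor(np.zeros(conv2_filters), requires_grad=True)
        self.flat_dim = conv2_filters * h * w
        self.mlp1 = Linear(self.flat_dim, mlp_hidden, rng)
        self.mlp2 = Linear(mlp_hidden, n_classes, rng)

    def params(self):
        ps = [self.channel_w] + self.embed.params()
        for layer in self.layers:
            ps += layer.params()
        ps += [self.conv1_w, self.conv1_b, self.conv2_w, self.conv2_b]
        ps += self.mlp1.params() + self.mlp2.params()
        return ps

    def encode(self, x: np.ndarray, mask, training: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
        """Input (B, C, T) -> encoder representation (B, n, d)."""
        rng = rng or np.random.default_rng(0)
        xt = Tensor(x)
        w = ad.reshape(self.channel_w, (1, self.n_channels, 1))
        weighted = ad.mul(xt, w)
        tokens = ad.transpose(weighted, (0, 2, 1))  # (B, T, C)
        s = ad.add(self.embed(tokens), self.pe)
        for layer in self.layers:
            s = layer(s, mask, training, rng)
        return s

    def forward(self, x: np.ndarray, mask, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        rng = rng or np.random.default_rng(0)
        s = self.encode(x, mask, training, rng)
        B = x.shape[0]
        img = ad.reshape(s, (B, 1, self.n_times, self.d_model))
        c = ad.maxpool2x2(ad.relu(ad.conv2d_valid(img, self.conv1_w, self.conv1_b)))
        c = ad.maxpool2x2(ad.relu(ad.conv2d_valid(c, self.conv2_w, self.conv2_b)))
        flat = ad.reshape(c, (B, self.flat_dim))
        hidden = ad.dropout(ad.relu(self.mlp1(flat)), self.p_drop, rng, training)
        return self.mlp2(hidden)

    # -- weight checkpointing for early stopping ------------------------------
    def get_weights(self):
        return [p.data.copy() for p in self.params()]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.params(), weights):
            p.data = w.copy()
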