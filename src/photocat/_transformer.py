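"""NumPy encoder-decoder transformer with hand-written backpropagation.

A compact float32 implementation of the standard post-norm transformer:
shared source/target embeddings with sinusoidal position encoding, multi-head
scaled dot-product attention (self, causal-self, and cross), position-wise
feed-forward sublayers, residual connections with layer normalization, and
inverted dropout. Every module implements an explicit ``backward`` that
mirrors its ``forward``; correctness is pinned by finite-difference gradient
checks in the test suite.

All randomness (initialization, dropout) flows through explicit
``numpy.random.Generator`` objects, so training is bit-reproducible for a
fixed seed and batch order.
"""

from __future__ import annotations

import numpy as np

NEG_INF = np.float32(-1e9)
_EPS = 1e-5


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray) -> None:
        self.v = value.astype(np.float32)
        self.g = np.zeros_like(self.v)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, shape).astype(np.float32)


def sinusoidal_positions(max_len: int, dim: int) -> np.ndarray:
    pos = np.arange(max_len)[:, None].astype(np.float64)
    i = np.arange(dim // 2)[None, :].astype(np.float64)
    angles = pos / np.power(10000.0, 2.0 * i / dim)
    pe = np.zeros((max_len, dim), dtype=np.float32)
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = x - x.max(axis=axis, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=axis, keepdims=True)


class Linear:
    def __init__(
        self, rng: np.random.Generator, d_in: int, d_out: int, bias: bool = True
    ) -> None:
        self.W = Param(_glorot(rng, (d_in, d_out)))
        self.b = Param(np.zeros(d_out, dtype=np.float32)) if bias else None
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.W.v
        if self.b is not None:
            y += self.b.v
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.W.g += x2.T @ dy2
        if self.b is not None:
            self.b.g += dy2.sum(axis=0)
        return dy @ self.W.v.T

    def params(self) -> list[Param]:
        return [self.W] if self.b is None else [self.W, self.b]


class LayerNorm:
    def __init__(self, dim: int) -> None:
        self.g = Param(np.ones(dim, dtype=np.float32))
        self.b = Param(np.zeros(dim, dtype=np.float32))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + _EPS)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.g.v * xhat + self.b.v

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.g.g += (dy * xhat).reshape(-1, dy.shape[-1]).sum(axis=0)
        self.b.g += dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        dxhat = dy * self.g.v
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)

    def params(self) -> list[Param]:
        return [self.g, self.b]


class Dropout:
    def __init__(self, p: float) -> None:
        self.p = p
        self._mask: np.ndarray | float = 1.0

    def forward(self, x: np.ndarray, rng: np.random.Generator, train: bool) -> np.ndarray:
        if not train or self.p <= 0.0:
            self._mask = 1.0
            return x
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


def _split_heads(x: np.ndarray, n_heads: int) -> np.ndarray:
    b, l, d = x.shape
    return x.reshape(b, l, n_heads, d // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x: np.ndarray) -> np.ndarray:
    b, h, l, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, l, h * dh)


class MultiHeadAttention:
    """Scaled dot-product attention with a fused, bias-free K/V projection
    (and fused Q/K/V when queries and keys come from the same tensor)."""

    def __init__(self, rng: np.random.Generator, dim: int, n_heads: int) -> None:
        if dim % n_heads != 0:
            raise ValueError(f"model_dim {dim} not divisible by n_heads {n_heads}")
        self.dim = dim
        self.n_heads = n_heads
        self.scale = np.float32(1.0 / np.sqrt(dim // n_heads))
        self.wq = Linear(rng, dim, dim, bias=False)
        self.wkv = Linear(rng, dim, 2 * dim, bias=False)
        self.wo = Linear(rng, dim, dim)
        self.last_probs: np.ndarray | None = None  # (B, H, Lq, Lk)
        self._cache = None

    def forward(
        self, q_in: np.ndarray, kv_in: np.ndarray, mask: np.ndarray | None
    ) -> np.ndarray:
        fused = q_in is kv_in
        kv = self.wkv.forward(kv_in)
        k = _split_heads(kv[..., : self.dim], self.n_heads)
        v = _split_heads(kv[..., self.dim :], self.n_heads)
        q = _split_heads(self.wq.forward(q_in), self.n_heads)
        scores = (q @ k.transpose(0, 1, 3, 2)) * self.scale
        if mask is not None:
            scores = scores + mask
        probs = softmax(scores)
        self.last_probs = probs
        ctx = probs @ v
        self._cache = (q, k, v, probs, fused)
        return self.wo.forward(_merge_heads(ctx))

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        q, k, v, probs, fused = self._cache
        dctx = _split_heads(self.wo.backward(dout), self.n_heads)
        dprobs = dctx @ v.transpose(0, 1, 3, 2)
        dv = probs.transpose(0, 1, 3, 2) @ dctx
        dscores = probs * (dprobs - (dprobs * probs).sum(axis=-1, keepdims=True))
        dscores *= self.scale
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q
        dkv_cat = np.concatenate([_merge_heads(dk), _merge_heads(dv)], axis=-1)
        dq_in = self.wq.backward(_merge_heads(dq))
        dkv = self.wkv.backward(dkv_cat)
        return dq_in, dkv

    def params(self) -> list[Param]:
        return [*self.wq.params(), *self.wkv.params(), *self.wo.params()]


class FeedForward:
    def __init__(self, rng: np.random.Generator, dim: int, hidden: int) -> None:
        self.l1 = Linear(rng, dim, hidden)
        self.l2 = Linear(rng, hidden, dim)
        self._h: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.l1.forward(x)
        self._h = h
        return self.l2.forward(np.maximum(h, 0.0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.l2.backward(dy)
        dh = dh * (self._h > 0.0)
        return self.l1.backward(dh)

    def params(self) -> list[Param]:
        return [*self.l1.params(), *self.l2.params()]


class EncoderLayer:
    """Self-attention + feed-forward block.

    ``pre_norm=False`` is the classic post-norm layout (LN after each residual
    add); ``pre_norm=True`` normalizes sublayer inputs instead, which trains
    more stably at small scale.
    """

    def __init__(self, rng, dim: int, n_heads: int, ffn: int, dropout: float,
                 pre_norm: bool = False) -> None:
        self.pre_norm = pre_norm
        self.attn = MultiHeadAttention(rng, dim, n_heads)
        self.ln1 = LayerNorm(dim)
        self.ffn = FeedForward(rng, dim, ffn)
        self.ln2 = LayerNorm(dim)
        self.d1 = Dropout(dropout)
        self.d2 = Dropout(dropout)

    def forward(self, x, mask, rng, train):
        if self.pre_norm:
            h = self.ln1.forward(x)
            x = x + self.d1.forward(self.attn.forward(h, h, mask), rng, train)
            x = x + self.d2.forward(self.ffn.forward(self.ln2.forward(x)), rng, train)
            return x
        x = self.ln1.forward(x + self.d1.forward(self.attn.forward(x, x, mask), rng, train))
        x = self.ln2.forward(x + self.d2.forward(self.ffn.forward(x), rng, train))
        return x

    def backward(self, dy):
        if self.pre_norm:
            dh = self.ffn.backward(self.d2.backward(dy))
            dy = dy + self.ln2.backward(dh)
            dq, dkv = self.attn.backward(self.d1.backward(dy))
            return dy + self.ln1.backward(dq + dkv)
        dy = self.ln2.backward(dy)
        dy = dy + self.ffn.backward(self.d2.backward(dy))
        dy = self.ln1.backward(dy)
        dq, dkv = self.attn.backward(self.d1.backward(dy))
        return dy + dq + dkv

    def params(self):
        return [*self.attn.params(), *self.ln1.params(), *self.ffn.params(), *self.ln2.params()]


class DecoderLayer:
    def __init__(self, rng, dim: int, n_heads: int, ffn: int, dropout: float,
                 pre_norm: bool = False) -> None:
        self.pre_norm = pre_norm
        self.self_attn = MultiHeadAttention(rng, dim, n_heads)
        self.ln1 = LayerNorm(dim)
        self.cross_attn = MultiHeadAttention(rng, dim, n_heads)
        self.ln2 = LayerNorm(dim)
        self.ffn = FeedForward(rng, dim, ffn)
        self.ln3 = LayerNorm(dim)
        self.d1 = Dropout(dropout)
        self.d2 = Dropout(dropout)
        self.d3 = Dropout(dropout)

    def forward(self, x, memory, self_mask, cross_mask, rng, train):
        if self.pre_norm:
            h = self.ln1.forward(x)
            x = x + self.d1.forward(self.self_attn.forward(h, h, self_mask), rng, train)
            x = x + self.d2.forward(
                self.cross_attn.forward(self.ln2.forward(x), memory, cross_mask), rng, train
            )
            x = x + self.d3.forward(self.ffn.forward(self.ln3.forward(x)), rng, train)
            return x
        x = self.ln1.forward(
            x + self.d1.forward(self.self_attn.forward(x, x, self_mask), rng, train)
        )
        x = self.ln2.forward(
            x + self.d2.forward(self.cross_attn.forward(x, memory, cross_mask), rng, train)
        )
        x = self.ln3.forward(x + self.d3.forward(self.ffn.forward(x), rng, train))
        return x

    def backward(self, dy):
        if self.pre_norm:
            dh = self.ffn.backward(self.d3.backward(dy))
            dy = dy + self.ln3.backward(dh)
            dq, dmem = self.cross_attn.backward(self.d2.backward(dy))
            dy = dy + self.ln2.backward(dq)
            dq, dkv = self.self_attn.backward(self.d1.backward(dy))
            return dy + self.ln1.backward(dq + dkv), dmem
        dy = self.ln3.backward(dy)
        dy = dy + self.ffn.backward(self.d3.backward(dy))
        dy = self.ln2.backward(dy)
        dq, dmem = self.cross_attn.backward(self.d2.backward(dy))
        dy = dy + dq
        dy = self.ln1.backward(dy)
        dq, dkv = self.self_attn.backward(self.d1.backward(dy))
        return dy + dq + dkv, dmem

    def params(self):
        return [
            *self.self_attn.params(), *self.ln1.params(),
            *self.cross_attn.params(), *self.ln2.params(),
            *self.ffn.params(), *self.ln3.params(),
        ]


class Transformer:
    """Encoder-decoder stack over a shared token vocabulary."""

    def __init__(
        self,
        rng: np.random.Generator,
        vocab_size: int,
        dim: int,
        n_heads: int,
        n_encoder_layers: int,
        n_decoder_layers: int,
        ffn_dim: int,
        dropout: float,
        max_len: int = 512,
        pre_norm: bool = False,
        tie_embedding: bool = False,
    ) -> None:
        if dim % n_heads != 0:
            raise ValueError(f"model_dim {dim} not divisible by n_heads {n_heads}")
        self.dim = dim
        self.vocab_size = vocab_size
        self.pre_norm = pre_norm
        self.tie_embedding = tie_embedding
        self.embed = Param(rng.normal(0.0, dim ** -0.5, (vocab_size, dim)).astype(np.float32))
        self.pos = sinusoidal_positions(max_len, dim)
        self.enc_drop = Dropout(dropout)
        self.dec_drop = Dropout(dropout)
        self.encoder = [
            EncoderLayer(rng, dim, n_heads, ffn_dim, dropout, pre_norm)
            for _ in range(n_encoder_layers)
        ]
        self.decoder = [
            DecoderLayer(rng, dim, n_heads, ffn_dim, dropout, pre_norm)
            for _ in range(n_decoder_layers)
        ]
        self.enc_ln = LayerNorm(dim) if pre_norm else None
        self.dec_ln = LayerNorm(dim) if pre_norm else None
        if tie_embedding:
            self.out_b = Param(np.zeros(vocab_size, dtype=np.float32))
            self.out = None
            self._out_y: np.ndarray | None = None
        else:
            self.out = Linear(rng, dim, vocab_size)
        self._cache = None

    # -- parameter plumbing -------------------------------------------------

    def params(self) -> list[Param]:
        out = [self.embed]
        for layer in (*self.encoder, *self.decoder):
            out.extend(layer.params())
        if self.enc_ln is not None:
            out.extend(self.enc_ln.params())
            out.extend(self.dec_ln.params())
        if self.tie_embedding:
            out.append(self.out_b)
        else:
            out.extend(self.out.params())
        return out

    def _project_out(self, y: np.ndarray) -> np.ndarray:
        if self.tie_embedding:
            self._out_y = y
            return y @ self.embed.v.T + self.out_b.v
        return self.out.forward(y)

    def _project_out_backward(self, dlogits: np.ndarray) -> np.ndarray:
        if self.tie_embedding:
            y = self._out_y
            d2 = dlogits.reshape(-1, dlogits.shape[-1])
            self.embed.g += d2.T @ y.reshape(-1, y.shape[-1])
            self.out_b.g += d2.sum(axis=0)
            return dlogits @ self.embed.v
        return self.out.backward(dlogits)

    def zero_grads(self) -> None:
        for p in self.params():
            p.g[...] = 0.0

    # -- masks --------------------------------------------------------------

    @staticmethod
    def padding_mask(ids: np.ndarray, pad_id: int) -> np.ndarray:
        """(B, 1, 1, L) additive mask hiding padded key positions."""
        return np.where(ids[:, None, None, :] == pad_id, NEG_INF, np.float32(0.0))

    @staticmethod
    def causal_mask(ids: np.ndarray, pad_id: int) -> np.ndarray:
        b, l = ids.shape
        tri = np.triu(np.full((l, l), NEG_INF, dtype=np.float32), k=1)
        pad = np.where(ids[:, None, None, :] == pad_id, NEG_INF, np.float32(0.0))
        return tri[None, None, :, :] + pad

    # -- forward / backward -------------------------------------------------

    def _embed(self, ids: np.ndarray) -> np.ndarray:
        x = self.embed.v[ids] * np.float32(np.sqrt(self.dim))
        return x + self.pos[: ids.shape[1]]

    def forward(
        self,
        src_ids: np.ndarray,
        tgt_in_ids: np.ndarray,
        pad_id: int,
        rng: np.random.Generator | None = None,
        train: bool = False,
    ) -> np.ndarray:
        """Teacher-forced logits (B, L_tgt, vocab)."""
        rng = rng or np.random.default_rng(0)
        src_mask = self.padding_mask(src_ids, pad_id)
        tgt_mask = self.causal_mask(tgt_in_ids, pad_id)
        x = self.enc_drop.forward(self._embed(src_ids), rng, train)
        for layer in self.encoder:
            x = layer.forward(x, src_mask, rng, train)
        if self.enc_ln is not None:
            x = self.enc_ln.forward(x)
        memory = x
        y = self.dec_drop.forward(self._embed(tgt_in_ids), rng, train)
        for layer in self.decoder:
            y = layer.forward(y, memory, tgt_mask, src_mask, rng, train)
        if self.dec_ln is not None:
            y = self.dec_ln.forward(y)
        logits = self._project_out(y)
        self._cache = (src_ids, tgt_in_ids)
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        src_ids, tgt_in_ids = self._cache
        dy = self._project_out_backward(dlogits)
        if self.dec_ln is not None:
            dy = self.dec_ln.backward(dy)
        dmem_total = 0.0
        for layer in reversed(self.decoder):
            dy, dmem = layer.backward(dy)
            dmem_total = dmem_total + dmem
        dy = self.dec_drop.backward(dy)
        np.add.at(self.embed.g, tgt_in_ids, dy * np.float32(np.sqrt(self.dim)))
        dx = dmem_total
        if self.enc_ln is not None:
            dx = self.enc_ln.backward(dx)
        for layer in reversed(self.encoder):
            dx = layer.backward(dx)
        dx = self.enc_drop.backward(dx)
        np.add.at(self.embed.g, src_ids, dx * np.float32(np.sqrt(self.dim)))

    def cross_attention_probs(self) -> np.ndarray:
        """Final-layer cross-attention probabilities from the last forward."""
        probs = self.decoder[-1].cross_attn.last_probs
        if probs is None:
            raise RuntimeError("no forward pass has been run")
        return probs


def label_smoothed_loss(
    logits: np.ndarray,
    target_ids: np.ndarray,
    pad_id: int,
    epsilon: float,
) -> tuple[float, np.ndarray]:
    """Mean label-smoothed cross-entropy over non-pad positions, with gradient.

    The smoothed target distribution places ``1 - epsilon`` on the gold token
    and spreads ``epsilon`` uniformly over the whole vocabulary; with
    ``epsilon = 0`` this is exactly the cross-entropy.
    """
    b, l, v = logits.shape
    flat = logits.reshape(-1, v).astype(np.float64)
    tgt = target_ids.reshape(-1)
    keep = tgt != pad_id
    n = int(keep.sum())
    if n == 0:
        raise ValueError("batch contains no non-pad target tokens")
    m = flat.max(axis=1, keepdims=True)
    logz = m + np.log(np.exp(flat - m).sum(axis=1, keepdims=True))
    logp = flat - logz
    gold = logp[np.arange(len(tgt)), tgt]
    smooth = logp.mean(axis=1)
    loss_tok = -(1.0 - epsilon) * gold - epsilon * smooth
    loss = float(loss_tok[keep].sum() / n)

    probs = np.exp(logp)
    q = np.full_like(probs, epsilon / v)
    q[np.arange(len(tgt)), tgt] += 1.0 - epsilon
    grad = (probs - q) / n
    grad[~keep] = 0.0
    return loss, grad.reshape(b, l, v).astype(np.float32)


def clip_gradients(params: list[Param], max_norm: float) -> float:
    """Global-norm gradient clipping; disabled when ``max_norm <= 0``."""
    total = float(np.sqrt(sum(float((p.g ** 2).sum()) for p in params)))
    if max_norm > 0.0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            p.g *= scale
    return total


class Adam:
    def __init__(self, params: list[Param], beta1: float, beta2: float, eps: float = 1e-9):
        self.params = params
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p.v) for p in params]
        self.v = [np.zeros_like(p.v) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * p.g
            v *= b2
            v += (1.0 - b2) * p.g ** 2
            p.v -= np.float32(lr) * (m / c1) / (np.sqrt(v / c2) + self.eps)
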