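"""Minimal NumPy neural-network engine for the transformer classifier.

Implements exactly the layers the encoder needs — token embedding with fixed
sinusoidal positions, multi-head self-attention with key padding masks,
LayerNorm, position-wise feed-forward, dropout, a flatten classification head
— each with an analytic backward pass, plus the Adam optimizer.  Gradients
are verified against central finite differences in the test suite.

All trainable tensors live in :class:`Param` objects; forward passes cache
what backward needs, so each layer instance handles one forward/backward pair
at a time (standard single-threaded training).
"""

from __future__ import annotations

import numpy as np

from .encode import positional_encoding

NEG_INF = -1e9  # additive attention mask for PAD keys


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    @property
    def size(self) -> int:
        return self.value.size


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(dtype)


class Linear:
    def __init__(self, rng, d_in: int, d_out: int, dtype=np.float32):
        self.W = Param(_xavier(rng, d_in, d_out, dtype))
        self.b = Param(np.zeros(d_out, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        self.W.grad += x2.T @ d2
        self.b.grad += d2.sum(axis=0)
        return dout @ self.W.value.T


class LayerNorm:
    def __init__(self, d: int, dtype=np.float32, eps: float = 1e-5):
        self.g = Param(np.ones(d, dtype=dtype))
        self.b = Param(np.zeros(d, dtype=dtype))
        self.eps = eps

    def params(self):
        return [self.g, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        return self.g.value * self._xhat + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, std = self._xhat, self._std
        flat = dout.reshape(-1, dout.shape[-1])
        self.g.grad += (dout * xhat).reshape(-1, dout.shape[-1]).sum(axis=0)
        self.b.grad += flat.sum(axis=0)
        dxhat = dout * self.g.value
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return (dxhat - m1 - xhat * m2) / std


class Dropout:
    """Inverted dropout; identity when rate is 0 or in inference mode."""

    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


def softmax_last(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadAttention:
    """Self-attention with key padding mask (PAD keys excluded everywhere)."""

    def __init__(self, rng, d_model: int, n_heads: int, dtype=np.float32):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.h = n_heads
        self.dh = d_model // n_heads
        self.q = Linear(rng, d_model, d_model, dtype)
        self.k = Linear(rng, d_model, d_model, dtype)
        self.v = Linear(rng, d_model, d_model, dtype)
        self.o = Linear(rng, d_model, d_model, dtype)

    def params(self):
        return self.q.params() + self.k.params() + self.v.params() + self.o.params()

    def _split(self, x):  # (B,L,D) -> (B,H,L,dh)
        B, L, _ = x.shape
        return x.reshape(B, L, self.h, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x):  # (B,H,L,dh) -> (B,L,D)
        B, H, L, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, L, H * dh)

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        q = self._split(self.q.forward(x))
        k = self._split(self.k.forward(x))
        v = self._split(self.v.forward(x))
        scores = np.matmul(q, k.transpose(0, 1, 3, 2)) / np.sqrt(self.dh)
        scores = scores + np.where(mask, 0.0, NEG_INF).astype(x.dtype)[:, None, None, :]
        p = softmax_last(scores)
        ctx = np.matmul(p, v)
        self._cache = (q, k, v, p)
        return self.o.forward(self._merge(ctx))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        q, k, v, p = self._cache
        dctx = self._split(self.o.backward(dout))
        dp = np.matmul(dctx, v.transpose(0, 1, 3, 2))
        dv = np.matmul(p.transpose(0, 1, 3, 2), dctx)
        dscores = p * (dp - (dp * p).sum(axis=-1, keepdims=True))
        dscores /= np.sqrt(self.dh)
        dq = np.matmul(dscores, k)
        dk = np.matmul(dscores.transpose(0, 1, 3, 2), q)
        dx = self.q.backward(self._merge(dq))
        dx += self.k.backward(self._merge(dk))
        dx += self.v.backward(self._merge(dv))
        return dx


class FeedForward:
    """Position-wise d_model → d_ff → d_model with ReLU."""

    def __init__(self, rng, d_model: int, d_ff: int, dtype=np.float32):
        self.l1 = Linear(rng, d_model, d_ff, dtype)
        self.l2 = Linear(rng, d_ff, d_model, dtype)

    def params(self):
        return self.l1.params() + self.l2.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.l1.forward(x)
        self._relu = h > 0
        return self.l2.forward(h * self._relu)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dh = self.l2.backward(dout) * self._relu
        return self.l1.backward(dh)


class EncoderBlock:
    """Post-LN transformer block: attention → add&norm → FFN → add&norm."""

    def __init__(self, rng, d_model, n_heads, d_ff, dropout, dtype=np.float32):
        self.attn = MultiHeadAttention(rng, d_model, n_heads, dtype)
        self.ln1 = LayerNorm(d_model, dtype)
        self.ffn = FeedForward(rng, d_model, d_ff, dtype)
        self.ln2 = LayerNorm(d_model, dtype)
        self.drop1 = Dropout(dropout)
        self.drop2 = Dropout(dropout)

    def params(self):
        return (
            self.attn.params() + self.ln1.params() + self.ffn.params() + self.ln2.params()
        )

    def forward(self, x, mask, train, rng):
        h = self.ln1.forward(x + self.drop1.forward(self.attn.forward(x, mask), train, rng))
        return self.ln2.forward(h + self.drop2.forward(self.ffn.forward(h), train, rng))

    def backward(self, dout):
        dh = self.ln2.backward(dout)
        dh = dh + self.ffn.backward(self.drop2.backward(dh))
        dx = self.ln1.backward(dh)
        return dx + self.attn.backward(self.drop1.backward(dx))


class TransformerClassifier:
    """Token embedding + sinusoidal positions → encoder stack → flatten head.

    The classification head zeroes encoder outputs at PAD positions before
    flattening, so padded content can never influence the score, then applies
    hidden (ReLU) and scalar output layers; the sigmoid lives in
    :meth:`forward` / the loss.
    """

    def __init__(self, config, seed: int = 0, dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.config = config
        self.dtype = dtype
        d = config.d_model
        scale = 1.0 / np.sqrt(d)
        self.embedding = Param(
            (rng.standard_normal((config.vocab_size, d)) * scale).astype(dtype)
        )
        self.pe = positional_encoding(config.max_len, d).astype(dtype)
        self.blocks = [
            EncoderBlock(rng, d, config.n_heads, config.d_ff, config.dropout, dtype)
            for _ in range(config.n_layers)
        ]
        self.drop_in = Dropout(config.dropout)
        self.head1 = Linear(rng, config.max_len * d, config.head_hidden, dtype)
        self.head2 = Linear(rng, config.head_hidden, 1, dtype)

    # ---- parameters ------------------------------------------------------
    def params(self) -> list[Param]:
        ps = [self.embedding]
        for blk in self.blocks:
            ps.extend(blk.params())
        ps.extend(self.head1.params())
        ps.extend(self.head2.params())
        return ps

    def parameter_count(self) -> int:
        return sum(p.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state, strict=True):
            p.value[...] = v

    # ---- forward / backward ---------------------------------------------
    def forward(
        self,
        ids: np.ndarray,
        mask: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Presentation scores in (0, 1) for a batch of token sequences."""
        self._ids = ids
        x = self.embedding.value[ids] + self.pe[None, : ids.shape[1]]
        x = self.drop_in.forward(x, train, rng)
        for blk in self.blocks:
            x = blk.forward(x, mask, train, rng)
        self._mask_f = mask[..., None].astype(self.dtype)
        x = x * self._mask_f  # PAD positions contribute nothing to the head
        self._flat_shape = x.shape
        flat = x.reshape(x.shape[0], -1)
        h = self.head1.forward(flat)
        self._head_relu = h > 0
        logits = self.head2.forward(h * self._head_relu)[:, 0]
        self._logits = logits.astype(np.float64)
        return 1.0 / (1.0 + np.exp(-self._logits))

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients given d(loss)/d(logits)."""
        dh = self.head2.backward(dlogits[:, None].astype(self.dtype))
        dflat = self.head1.backward(dh * self._head_relu)
        dx = dflat.reshape(self._flat_shape) * self._mask_f
        for blk in reversed(self.blocks):
            dx = blk.backward(dx)
        dx = self.drop_in.backward(dx)
        np.add.at(self.embedding.grad, self._ids, dx)


class Adam:
    """Adam with bias correction; one slot pair per parameter."""

    def __init__(self, params: list[Param], lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value, dtype=np.float32) for p in params]
        self.v = [np.zeros_like(p.value, dtype=np.float32) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(np.float32)
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p.value -= (self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)).astype(
                p.value.dtype
            )
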