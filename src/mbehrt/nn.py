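"""Neural building blocks: transformer encoder over four aligned input layers
(token / modality / delay / position), multi-head self- and cross-attention,
and an Adam optimizer.  Built on :mod:`mbehrt.autograd`.

Initialization is N(0, 0.02) throughout (BERT convention); layer norm is
pre-norm, which trains stably without a warm-up schedule at the depths used
here.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, gather_rows, gelu, log_softmax, no_grad, sigmoid, softmax, softplus, take_along_last

INIT_STD = 0.02


class Module:
    """Lightweight parameter container with recursive traversal."""

    def named_parameters(self, prefix: str = ""):
        for name, attr in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(attr, Tensor) and attr.requires_grad:
                yield key, attr
            elif isinstance(attr, Module):
                yield from attr.named_parameters(f"{key}.")
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            raise ValueError(
                f"parameter mismatch: missing {set(own) - set(state)}, "
                f"unexpected {set(state) - set(own)}"
            )
        for k, v in state.items():
            if own[k].data.shape != v.shape:
                raise ValueError(f"shape mismatch for {k}: {own[k].data.shape} vs {v.shape}")
            own[k].data = np.asarray(v, dtype=np.float32).copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Tensor(rng.normal(0.0, INIT_STD, (d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Embedding(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0.0, INIT_STD, (n, d)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return gather_rows(self.weight, idx)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gamma + self.beta


def _split_heads(x: Tensor, n_heads: int) -> Tensor:
    b, t, d = x.shape
    return x.reshape(b, t, n_heads, d // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x: Tensor) -> Tensor:
    b, h, t, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, t, h * dh)


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor, key_mask: np.ndarray | None) -> Tensor:
    """q,k,v: (B, H, T, dh); key_mask: (B, Tk) with 1 = attendable."""
    dh = q.shape[-1]
    scores = q @ k.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(dh))
    if key_mask is not None:
        bias = (1.0 - key_mask[:, None, None, :].astype(np.float32)) * -1e9
        scores = scores + Tensor(bias)
    return softmax(scores, axis=-1) @ v


class Attention(Module):
    """Multi-head attention; self-attention when query source == key source."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator, d_query: int | None = None):
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.wq = Linear(d_query or d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def __call__(self, query: Tensor, keys: Tensor, key_mask: np.ndarray | None = None) -> Tensor:
        q = _split_heads(self.wq(query), self.n_heads)
        k = _split_heads(self.wk(keys), self.n_heads)
        v = _split_heads(self.wv(keys), self.n_heads)
        return self.wo(_merge_heads(scaled_dot_attention(q, k, v, key_mask)))


class FeedForward(Module):
    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator):
        self.fc1 = Linear(d_model, d_ff, rng)
        self.fc2 = Linear(d_ff, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))


class TransformerBlock(Module):
    def __init__(self, d_model: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        self.ln1 = LayerNorm(d_model)
        self.attn = Attention(d_model, n_heads, rng)
        self.ln2 = LayerNorm(d_model)
        self.ff = FeedForward(d_model, d_ff, rng)

    def __call__(self, x: Tensor, key_mask: np.ndarray | None) -> Tensor:
        h = self.ln1(x)
        x = x + self.attn(h, h, key_mask)
        x = x + self.ff(self.ln2(x))
        return x


class TransformerStack(Module):
    def __init__(self, n_layers: int, d_model: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        self.blocks = [TransformerBlock(d_model, n_heads, d_ff, rng) for _ in range(n_layers)]
        self.ln_out = LayerNorm(d_model)

    def __call__(self, x: Tensor, key_mask: np.ndarray | None = None) -> Tensor:
        for blk in self.blocks:
            x = blk(x, key_mask)
        return self.ln_out(x)


class TrajectoryEncoder(Module):
    """BERT-style encoder whose input embedding is the sum of four learned
    layers: token identity, modality (feature type), inter-visit delay bucket
    and absolute position.  The modality layer is what lets missing features
    simply be skipped instead of imputed."""

    def __init__(self, vocab_size: int, n_modalities: int, n_delays: int,
                 max_len: int, d_model: int, n_heads: int, d_ff: int,
                 n_layers: int, rng: np.random.Generator):
        self.tok = Embedding(vocab_size, d_model, rng)
        self.mod = Embedding(n_modalities, d_model, rng)
        self.delay = Embedding(n_delays, d_model, rng)
        self.pos = Embedding(max_len, d_model, rng)
        self.stack = TransformerStack(n_layers, d_model, n_heads, d_ff, rng)
        self.max_len = max_len
        self.d_model = d_model

    def embed_inputs(self, token_ids, modality_ids, delay_ids, positions) -> Tensor:
        return (self.tok(token_ids) + self.mod(modality_ids)
                + self.delay(delay_ids) + self.pos(positions))

    def __call__(self, token_ids, modality_ids, delay_ids, positions, attn_mask) -> Tensor:
        x = self.embed_inputs(token_ids, modality_ids, delay_ids, positions)
        return self.stack(x, attn_mask)

    def forward_from_embeddings(self, x: Tensor, attn_mask) -> Tensor:
        """Entry point for attribution: run the stack on explicit input
        embeddings (so gradients w.r.t. the inputs are available)."""
        return self.stack(x, attn_mask)


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean NLL over rows; logits (N, V), integer targets (N,)."""
    ls = log_softmax(logits, axis=-1)
    return -take_along_last(ls, targets).mean()


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy on raw logits."""
    t = np.asarray(targets, dtype=np.float32)
    return (softplus(logits) - logits * Tensor(t)).mean()


__all__ = [
    "Adam", "Attention", "Embedding", "FeedForward", "LayerNorm", "Linear",
    "Module", "TrajectoryEncoder", "TransformerBlock", "TransformerStack",
    "bce_with_logits", "concat", "cross_entropy", "gelu", "no_grad",
    "scaled_dot_attention", "sigmoid", "softmax",
]
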