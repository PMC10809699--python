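"""Neural-network building blocks for the sequence classifiers.

Layers are thin compositions of :class:`~sepsishorizon._autodiff.Tensor`
primitives: linear maps, mask-aware RNN/LSTM recurrences, a 1-D convolution
along time, multi-head self-attention with key masking, layer norm, and an
Adam optimizer.  Every layer takes an explicit ``rng``
(:class:`numpy.random.Generator`) for initialization so training is
bit-reproducible from a seed.

Windows are left-padded: a boolean ``valid`` array of shape (B, T) marks the
real (non-padding) time steps.  Recurrences hold their state frozen at zero
through padded steps, attention masks padded keys, and pooling averages over
valid steps only — together this makes the classifiers exactly invariant to
how much left padding a window carries.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat_time

__all__ = [
    "Module", "Linear", "LayerNorm", "RNN", "LSTM", "Conv1dTime",
    "MultiHeadSelfAttention", "TransformerEncoderLayer", "Adam",
    "masked_mean_pool", "last_valid_state", "positional_encoding_from_end",
    "dropout", "softmax_cross_entropy",
]


class Module:
    """Base class: collects parameters from attributes (recursively)."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in self.__dict__.values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state length does not match parameter count")
        for p, arr in zip(params, state):
            p.data = arr.copy()


def _collect(value):
    if isinstance(value, Tensor):
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_dim + out_dim))
        self.W = Tensor(rng.normal(0.0, scale, size=(in_dim, out_dim)), requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.bias = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gain + self.bias


class RNN(Module):
    """Plain tanh recurrence over time, state frozen through padded steps."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        self.hidden_size = hidden_size
        sx = np.sqrt(2.0 / (input_size + hidden_size))
        sh = np.sqrt(1.0 / hidden_size)
        self.Wx = Tensor(rng.normal(0.0, sx, size=(input_size, hidden_size)), requires_grad=True)
        self.Wh = Tensor(rng.normal(0.0, sh, size=(hidden_size, hidden_size)), requires_grad=True)
        self.b = Tensor(np.zeros(hidden_size), requires_grad=True)

    def __call__(self, x: Tensor, valid: np.ndarray) -> Tensor:
        B, T, _ = x.shape
        x_proj = x @ self.Wx + self.b  # (B, T, H)
        h = Tensor(np.zeros((B, self.hidden_size)))
        outs = []
        for t in range(T):
            v = valid[:, t:t + 1].astype(np.float64)  # (B, 1) constant
            h_new = (x_proj[:, t, :] + h @ self.Wh).tanh()
            h = h_new * v + h * (1.0 - v)
            outs.append(h.reshape(B, 1, self.hidden_size))
        return concat_time(outs)


class LSTM(Module):
    """Long short-term memory recurrence; cell and hidden state are held at
    their previous value (zero before the first valid step) on padded steps,
    so left padding never touches the computation on real rows."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        self.hidden_size = hidden_size
        sx = np.sqrt(2.0 / (input_size + hidden_size))
        sh = np.sqrt(1.0 / hidden_size)
        H = hidden_size
        self.Wx = Tensor(rng.normal(0.0, sx, size=(input_size, 4 * H)), requires_grad=True)
        self.Wh = Tensor(rng.normal(0.0, sh, size=(H, 4 * H)), requires_grad=True)
        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0  # forget-gate bias starts open
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor, valid: np.ndarray) -> Tensor:
        B, T, _ = x.shape
        H = self.hidden_size
        x_proj = x @ self.Wx + self.b  # (B, T, 4H)
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outs = []
        for t in range(T):
            v = valid[:, t:t + 1].astype(np.float64)
            gates = x_proj[:, t, :] + h @ self.Wh
            i = gates[:, 0 * H:1 * H].sigmoid()
            f = gates[:, 1 * H:2 * H].sigmoid()
            g = gates[:, 2 * H:3 * H].tanh()
            o = gates[:, 3 * H:4 * H].sigmoid()
            c_new = f * c + i * g
            h_new = o * c_new.tanh()
            c = c_new * v + c * (1.0 - v)
            h = h_new * v + h * (1.0 - v)
            outs.append(h.reshape(B, 1, H))
        return concat_time(outs)


class Conv1dTime(Module):
    """1-D convolution along the time axis with same-length zero padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.kernel = kernel
        scale = np.sqrt(2.0 / (kernel * in_channels + out_channels))
        self.W = Tensor(rng.normal(0.0, scale, size=(kernel * in_channels, out_channels)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, N = x.shape
        half = self.kernel // 2
        padded = x.pad_time(half, half)
        idx = np.arange(T)[:, None] + np.arange(self.kernel)[None, :]  # (T, k)
        patches = padded.take_time(idx)                 # (B, T, k, N)
        patches = patches.reshape(B, T, self.kernel * N)
        return patches @ self.W + self.b


class MultiHeadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.q = Linear(d_model, d_model, rng)
        self.k = Linear(d_model, d_model, rng)
        self.v = Linear(d_model, d_model, rng)
        self.out = Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor, valid: np.ndarray) -> Tensor:
        B, T, D = x.shape
        h, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, T, h, dh).transpose(0, 2, 1, 3)  # (B, h, T, dh)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))  # (B, h, T, T)
        key_bias = np.where(valid[:, None, None, :], 0.0, -1e9)
        attn = (scores + key_bias).softmax(axis=-1)
        mixed = attn @ v                                # (B, h, T, dh)
        mixed = mixed.transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.out(mixed)


class TransformerEncoderLayer(Module):
    """Pre-norm encoder block: x + attn(LN(x)); x + FFN(LN(x))."""

    def __init__(self, d_model: int, n_heads: int, ff_dim: int,
                 dropout_p: float, rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, ff_dim, rng)
        self.ff2 = Linear(ff_dim, d_model, rng)
        self.dropout_p = dropout_p

    def __call__(self, x: Tensor, valid: np.ndarray, rng=None, training=False) -> Tensor:
        a = self.attn(self.ln1(x), valid)
        x = x + dropout(a, self.dropout_p, rng, training)
        f = self.ff2(self.ff1(self.ln2(x)).relu())
        return x + dropout(f, self.dropout_p, rng, training)


def positional_encoding_from_end(T: int, d_model: int) -> np.ndarray:
    """Sinusoidal positional code indexed by distance from the window end.

    Anchoring positions at the end (position of row t is T-1-t) keeps the
    code of every real row unchanged when extra left padding is added, which
    preserves the padding-invariance contract.
    """
    pos = (T - 1 - np.arange(T))[:, None].astype(np.float64)
    i = np.arange(d_model)[None, :]
    angles = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    pe = np.zeros((T, d_model))
    pe[:, 0::2] = np.sin(angles[:, 0::2])
    pe[:, 1::2] = np.cos(angles[:, 1::2])
    return pe


def masked_mean_pool(x: Tensor, valid: np.ndarray) -> Tensor:
    """Average over valid time steps only: (B, T, D) -> (B, D)."""
    w = valid.astype(np.float64)[:, :, None]
    counts = np.maximum(w.sum(axis=1), 1.0)  # (B, 1)
    return (x * w).sum(axis=1) * (1.0 / counts)


def last_valid_state(x: Tensor, valid: np.ndarray) -> Tensor:
    """Pick each sequence's hidden state at its last valid step."""
    B = x.shape[0]
    last = valid.shape[1] - 1 - np.argmax(valid[:, ::-1], axis=1)
    return x[np.arange(B), last, :]


def dropout(x: Tensor, p: float, rng, training: bool) -> Tensor:
    if not training or p <= 0.0 or rng is None:
        return x
    keep = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * keep


def softmax_cross_entropy(logits: Tensor, y: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer labels under softmax logits."""
    logp = logits.log_softmax(axis=-1)
    picked = logp[np.arange(logits.shape[0]), y]
    return -picked.mean()


class Adam:
    """Adam with bias correction and decoupled (AdamW-style) weight decay.

    Decay is not applied through the gradient moments; it directly shrinks
    weights each step, so parameters that receive no persistent gradient
    signal (e.g. input weights of uninformative channels) decay toward zero.
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

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
            if self.weight_decay > 0:
                p.data = p.data - self.lr * self.weight_decay * p.data

    def zero_grad(self):
        for p in self.params:
            p.grad = None
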