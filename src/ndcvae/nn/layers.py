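"""Neural layers built on the tensor engine: dense, LSTM, layer norm, attention."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat

__all__ = ["Module", "Linear", "LSTM", "LayerNorm", "MultiHeadAttention"]


class Module:
    """Base class: parameter registration and flat parameter access."""

    def parameters(self) -> list[Tensor]:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Named parameter arrays, keys stable across runs (insertion order)."""
        out = {}
        for i, p in enumerate(self.parameters()):
            out[f"param_{i:04d}"] = p.data
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            src = arrays[f"param_{i:04d}"]
            if src.shape != p.data.shape:
                raise ValueError(f"shape mismatch for param_{i:04d}")
            p.data = np.asarray(src, dtype=np.float64).copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Tensor(_glorot(rng, n_in, n_out), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def lstm_sequence(
    x: Tensor, w_ih: Tensor, w_hh: Tensor, bias: Tensor
) -> Tensor:
    """Fused LSTM over a full sequence with hand-written backpropagation
    through time.

    ``x`` is (batch, time, n_in); returns the hidden states (batch, time,
    n_hidden) as a single graph node.  The recurrence is the classic LSTM
    with gate order input, forget, cell, output; the initial hidden and cell
    states are zero.  Fusing the unroll into one node keeps the graph small
    and the per-step work in vectorized numpy.
    """
    n_batch, n_time, n_in = x.shape
    nh = w_hh.shape[0]
    wi, wh, b = w_ih.data, w_hh.data, bias.data
    pre_in = x.data.reshape(-1, n_in) @ wi + b  # (B*T, 4H)
    pre_in = pre_in.reshape(n_batch, n_time, 4 * nh)

    gi = np.empty((n_batch, n_time, nh))
    gf = np.empty_like(gi)
    gg = np.empty_like(gi)
    go = np.empty_like(gi)
    cs = np.empty_like(gi)
    tanh_c = np.empty_like(gi)
    hs = np.empty_like(gi)
    h = np.zeros((n_batch, nh))
    c = np.zeros((n_batch, nh))
    for t in range(n_time):
        pre = pre_in[:, t] + h @ wh
        i = _sigmoid(pre[:, :nh])
        f = _sigmoid(pre[:, nh : 2 * nh])
        g = np.tanh(pre[:, 2 * nh : 3 * nh])
        o = _sigmoid(pre[:, 3 * nh :])
        c_prev = c
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        gi[:, t], gf[:, t], gg[:, t], go[:, t] = i, f, g, o
        cs[:, t], tanh_c[:, t], hs[:, t] = c, tc, h

    def backward(grad_hs: np.ndarray) -> None:
        dpre = np.empty((n_batch, n_time, 4 * nh))
        dh_next = np.zeros((n_batch, nh))
        dc_next = np.zeros((n_batch, nh))
        for t in range(n_time - 1, -1, -1):
            dh = grad_hs[:, t] + dh_next
            i, f, g, o = gi[:, t], gf[:, t], gg[:, t], go[:, t]
            tc = tanh_c[:, t]
            dc = dh * o * (1.0 - tc * tc) + dc_next
            c_prev = cs[:, t - 1] if t > 0 else np.zeros((n_batch, nh))
            dpre_t = dpre[:, t]
            dpre_t[:, :nh] = dc * g * i * (1.0 - i)
            dpre_t[:, nh : 2 * nh] = dc * c_prev * f * (1.0 - f)
            dpre_t[:, 2 * nh : 3 * nh] = dc * i * (1.0 - g * g)
            dpre_t[:, 3 * nh :] = dh * tc * o * (1.0 - o)
            dh_next = dpre_t @ wh.T
            dc_next = dc * f
        dpre_flat = dpre.reshape(-1, 4 * nh)
        if x.requires_grad:
            x._accumulate((dpre_flat @ wi.T).reshape(n_batch, n_time, n_in))
        if w_ih.requires_grad:
            w_ih._accumulate(x.data.reshape(-1, n_in).T @ dpre_flat)
        if w_hh.requires_grad:
            h_prev = np.concatenate(
                [np.zeros((n_batch, 1, nh)), hs[:, :-1]], axis=1
            )
            w_hh._accumulate(h_prev.reshape(-1, nh).T @ dpre_flat)
        if bias.requires_grad:
            bias._accumulate(dpre_flat.sum(axis=0))

    out = Tensor(hs)
    if any(t.requires_grad for t in (x, w_ih, w_hh, bias)):
        out.requires_grad = True
        out._prev = (x, w_ih, w_hh, bias)
        out._backward = backward
    return out


class LSTM(Module):
    """Single-layer LSTM unrolled over time.

    Input ``x`` has shape (batch, time, n_in); returns per-step hidden states
    (batch, time, n_hidden) and the final hidden state (batch, n_hidden).
    Gate order in the fused weight matrices: input, forget, cell, output.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        self.w_ih = Tensor(_glorot(rng, n_in, 4 * n_hidden), requires_grad=True)
        self.w_hh = Tensor(_glorot(rng, n_hidden, 4 * n_hidden), requires_grad=True)
        bias = np.zeros(4 * n_hidden)
        bias[n_hidden : 2 * n_hidden] = 1.0  # forget-gate bias 1: remember by default
        self.bias = Tensor(bias, requires_grad=True)

    def __call__(self, x: Tensor):
        hs = lstm_sequence(x, self.w_ih, self.w_hh, self.bias)
        return hs, hs[:, -1, :]


class LayerNorm(Module):
    def __init__(self, n_features: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(n_features), requires_grad=True)
        self.shift = Tensor(np.zeros(n_features), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gain + self.shift


class MultiHeadAttention(Module):
    """Scaled dot-product self-attention with ``n_heads`` heads."""

    def __init__(self, n_embed: int, n_heads: int, rng: np.random.Generator):
        if n_embed % n_heads:
            raise ValueError("n_embed must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = n_embed // n_heads
        self.proj_q = Linear(n_embed, n_embed, rng)
        self.proj_k = Linear(n_embed, n_embed, rng)
        self.proj_v = Linear(n_embed, n_embed, rng)
        self.proj_out = Linear(n_embed, n_embed, rng)

    def __call__(self, x: Tensor) -> Tensor:
        n_batch, n_time, n_embed = x.shape

        def split_heads(t: Tensor) -> Tensor:
            return t.reshape(n_batch, n_time, self.n_heads, self.d_head).transpose(
                0, 2, 1, 3
            )

        q = split_heads(self.proj_q(x))
        k = split_heads(self.proj_k(x))
        v = split_heads(self.proj_v(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_head))
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(n_batch, n_time, n_embed)
        return self.proj_out(out)
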