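"""Neural building blocks on top of the autodiff engine.

Layers own their :class:`~drpgraph.autodiff.Parameter` leaves and expose
``parameters()`` for the optimizer and ``state_dict()`` /
``load_state_dict()`` for checkpointing. Initialization is Glorot-style
and fully determined by the RNG passed to the constructor.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor, concat


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Tiny module base: children discovered via attributes."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Parameter):
                        params.append(item)
                    elif isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out[key] = value.data.copy()
            elif isinstance(value, Module):
                out.update(value.state_dict(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Parameter):
                        out[f"{key}.{i}"] = item.data.copy()
                    elif isinstance(item, Module):
                        out.update(item.state_dict(prefix=f"{key}.{i}."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                value.data = np.asarray(state[key], dtype=np.float64).copy()
            elif isinstance(value, Module):
                value.load_state_dict(state, prefix=key + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Parameter):
                        item.data = np.asarray(state[f"{key}.{i}"], dtype=np.float64).copy()
                    elif isinstance(item, Module):
                        item.load_state_dict(state, prefix=f"{key}.{i}.")


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Parameter(glorot(rng, in_dim, out_dim))
        self.bias = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """1-D convolution (single input channel) implemented via im2col.

    Input shape (batch, length); output (batch, out_channels, out_len).
    """

    def __init__(self, out_channels: int, kernel: int, stride: int, rng: np.random.Generator):
        self.kernel = kernel
        self.stride = stride
        self.out_channels = out_channels
        self.weight = Parameter(glorot(rng, kernel, out_channels, shape=(kernel, out_channels)))
        self.bias = Parameter(np.zeros(out_channels))

    def out_len(self, length: int) -> int:
        return (length - self.kernel) // self.stride + 1

    def __call__(self, x: Tensor) -> Tensor:
        b, length = x.shape
        n_win = self.out_len(length)
        if n_win < 1:
            raise ValueError(f"input length {length} shorter than kernel {self.kernel}")
        idx = (np.arange(n_win)[:, None] * self.stride + np.arange(self.kernel)[None, :]).ravel()
        cols = _gather_cols(x, idx).reshape(b * n_win, self.kernel)
        out = cols @ self.weight + self.bias          # (b*n_win, out_ch)
        return out.reshape(b, n_win, self.out_channels)


def _gather_cols(x: Tensor, index: np.ndarray) -> Tensor:
    """Column gather with repetition, differentiable."""
    index = np.asarray(index, dtype=np.intp)

    def bwd(g):
        acc = np.zeros_like(x.data)
        np.add.at(acc.T, index, g.T)
        x._accumulate(acc)

    req = x.requires_grad
    return Tensor(x.data[:, index], req, (x,), bwd if req else None)


def adaptive_avg_pool(x: Tensor, target: int) -> Tensor:
    """Average-pool axis 1 of a (b, n, c) tensor into exactly ``target`` bins.

    Bins are contiguous [floor(i*n/target), max(lo+1, floor((i+1)*n/target)))
    ranges; when n < target some inputs are shared between bins, so the
    output width target*c is independent of the input length.
    """
    b, n, c = x.shape
    pieces = []
    for i in range(target):
        lo = (i * n) // target
        hi = max(lo + 1, ((i + 1) * n) // target)
        seg = _slice_axis1(x, lo, hi)
        pieces.append(seg.mean(axis=1).reshape(b, c))
    return concat(pieces, axis=1)


def _slice_axis1(x: Tensor, lo: int, hi: int) -> Tensor:
    def bwd(g):
        acc = np.zeros_like(x.data)
        acc[:, lo:hi] = g
        x._accumulate(acc)

    req = x.requires_grad
    return Tensor(x.data[:, lo:hi], req, (x,), bwd if req else None)


class MLP(Module):
    """ReLU MLP; final layer linear."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x


class Adam:
    """Adam with decoupled-style L2 weight decay folded into the gradient."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
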