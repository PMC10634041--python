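"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package's model stack (1-D/3-D convolutional attention channels, gated
recurrent units, the fusion decoder) is small enough that a purpose-built
tape-based engine is both transparent and fast on a single CPU.  Tensors wrap
numpy arrays and record a backward closure; :func:`backward` runs a
topological sweep.  Layers follow the familiar ``Module`` idiom with
``parameters()``, ``train()``/``eval()`` and flat ``state_dict`` I/O so that
trained models round-trip through ``.npz`` checkpoints.

Only the operations the model needs are implemented; every backward rule is
covered by gradient checks in the test-suite.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "stack",
    "softmax",
    "Module",
    "Linear",
    "Conv1d",
    "Conv3d",
    "Dropout",
    "GRUCell",
    "GRU",
    "MLP",
    "Adam",
]


class Tensor:
    """A numpy array with an attached gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd ----------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Back-propagate from this tensor (defaults to d(self)/d(self)=1)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative DFS: graphs can be deep (recurrent unrolls)
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            pending = [p for p in node._parents if id(p) not in seen and p.requires_grad]
            if pending:
                stack_.extend(pending)
            else:
                seen.add(id(node))
                topo.append(node)
                stack_.pop()
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accumulate(-g) if self.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = _bw
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def _bw(g):
            a, b = self.data, other.data
            if self.requires_grad:
                if b.ndim == 1:
                    ga = np.multiply.outer(g, b) if g.ndim else g * b
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                self._accumulate(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                if a.ndim == 1:
                    gb = np.multiply.outer(a, g) if g.ndim else a * g
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, b.shape))

        out._backward = _bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def _bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = _bw
        return out

    # -- shaping -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = (
            lambda g: self._accumulate(g.reshape(self.data.shape))
            if self.requires_grad
            else None
        )
        return out

    def flatten(self):
        return self.reshape(-1)

    def transpose(self, *axes):
        ax = axes or None
        out = Tensor(np.transpose(self.data, ax), parents=(self,))
        inv = np.argsort(ax) if ax else None

        def _bw(g):
            if self.requires_grad:
                self._accumulate(np.transpose(g, inv))

        out._backward = _bw
        return out

    @property
    def T(self):
        return self.transpose()

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def _bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- nonlinearities ----------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))
        out._backward = (
            lambda g: self._accumulate(g * out.data) if self.requires_grad else None
        )
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = (
            lambda g: self._accumulate(g / self.data) if self.requires_grad else None
        )
        return out

    def sqrt(self):
        return self**0.5

    def tanh(self):
        out = Tensor(np.tanh(self.data), parents=(self,))
        out._backward = (
            lambda g: self._accumulate(g * (1.0 - out.data**2))
            if self.requires_grad
            else None
        )
        return out

    def sigmoid(self):
        out = Tensor(_sigmoid(self.data), parents=(self,))
        out._backward = (
            lambda g: self._accumulate(g * out.data * (1.0 - out.data))
            if self.requires_grad
            else None
        )
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = (
            lambda g: self._accumulate(g * (self.data > 0))
            if self.requires_grad
            else None
        )
        return out

    def maximum(self, floor: float):
        """Elementwise max with a constant (hinge)."""
        out = Tensor(np.maximum(self.data, floor), parents=(self,))
        out._backward = (
            lambda g: self._accumulate(g * (self.data > floor))
            if self.requires_grad
            else None
        )
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    g = np.asarray(g)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = _bw
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), parents=tuple(tensors))

    def _bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    out._backward = _bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(np.max(x.data, axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------


class Module:
    """Base class: parameter discovery, mode switching, flat state dicts."""

    def __init__(self):
        self.training = True

    def _children(self):
        for name, val in vars(self).items():
            yield name, val

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                params.append(p)
        return params

    def named_parameters(self, prefix: str = ""):
        for name, val in self._children():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{key}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{key}.{i}", item
            elif isinstance(val, dict):
                for k, item in val.items():
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{k}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{key}.{k}", item

    def train(self):
        self._set_mode(True)
        return self

    def eval(self):
        self._set_mode(False)
        return self

    def _set_mode(self, flag: bool):
        self.training = flag
        for _, val in self._children():
            if isinstance(val, Module):
                val._set_mode(flag)
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        item._set_mode(flag)
            elif isinstance(val, dict):
                for item in val.values():
                    if isinstance(item, Module):
                        item._set_mode(flag)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        named = dict(self.named_parameters())
        if set(named) != set(state):
            missing = set(named) ^ set(state)
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in named.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _glorot(rng: np.random.Generator, *shape) -> np.ndarray:
    fan_in = shape[-2] if len(shape) > 1 else shape[0]
    fan_out = shape[-1]
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Tensor(_glorot(rng, in_features, out_features), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = as_tensor(x) @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Dropout(Module):
    """Inverted dropout; draws from an injectable generator for determinism."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return as_tensor(x)
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return as_tensor(x) * Tensor(keep)


class Conv1d(Module):
    """1-D convolution over the last axis of a (batch, channels, length) input.

    ``padding='same'`` pads so the output length is ceil(length / stride),
    which lets short feature vectors survive a stacked stride-2 pyramid.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1,
                 padding: int | str = "same"):
        super().__init__()
        scale = math.sqrt(2.0 / (in_channels * kernel_size))
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(out_channels, in_channels, kernel_size)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.stride = int(stride)
        self.kernel_size = int(kernel_size)
        self.padding = padding

    def _pad_amount(self, length: int) -> tuple[int, int]:
        if self.padding == "same":
            out_len = -(-length // self.stride)
            total = max((out_len - 1) * self.stride + self.kernel_size - length, 0)
            return total // 2, total - total // 2
        p = int(self.padding)
        return p, p

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        b, cin, length = x.shape
        lo, hi = self._pad_amount(length)
        if length + lo + hi < self.kernel_size:
            raise ValueError(
                f"input length {length} shorter than kernel {self.kernel_size} "
                f"after padding"
            )
        xp = np.pad(x.data, ((0, 0), (0, 0), (lo, hi)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel_size, axis=2)
        win = win[:, :, :: self.stride, :]  # (b, cin, lout, k)
        out_data = np.tensordot(win, self.weight.data, axes=([1, 3], [1, 2]))
        out_data = np.ascontiguousarray(np.moveaxis(out_data, 2, 1))  # (b, cout, lout)
        out = Tensor(out_data + self.bias.data[None, :, None],
                     parents=(x, self.weight, self.bias))
        stride, k = self.stride, self.kernel_size
        lout = out_data.shape[2]

        def _bw(g):
            if self.bias.requires_grad:
                self.bias._accumulate(g.sum(axis=(0, 2)))
            if self.weight.requires_grad:
                gw = np.tensordot(g, win, axes=([0, 2], [0, 2]))  # (cout, cin, k)
                self.weight._accumulate(gw)
            if x.requires_grad:
                gxp = np.zeros_like(xp)
                for kk in range(k):
                    contrib = np.tensordot(g, self.weight.data[:, :, kk],
                                           axes=([1], [0]))  # (b, lout, cin)
                    gxp[:, :, kk : kk + stride * lout : stride] += np.moveaxis(
                        contrib, 2, 1
                    )
                x._accumulate(gxp[:, :, lo : lo + length])

        out._backward = _bw
        return out


class Conv3d(Module):
    """3-D convolution over (batch, channels, X, Y, Z) volumes."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 1):
        super().__init__()
        k = int(kernel_size)
        scale = math.sqrt(2.0 / (in_channels * k**3))
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(out_channels, in_channels, k, k, k)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.stride = int(stride)
        self.kernel_size = k
        self.padding = int(padding)

    def forward(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        b, cin, *spatial = x.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        if any(dim + 2 * p < k for dim in spatial):
            raise ValueError(f"volume extents {spatial} too small for kernel {k}")
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        win = win[:, :, ::s, ::s, ::s]  # (b, cin, xo, yo, zo, k, k, k)
        out_data = np.tensordot(
            win, self.weight.data, axes=([1, 5, 6, 7], [1, 2, 3, 4])
        )  # (b, xo, yo, zo, cout)
        out_data = np.ascontiguousarray(np.moveaxis(out_data, 4, 1))
        out = Tensor(out_data + self.bias.data[None, :, None, None, None],
                     parents=(x, self.weight, self.bias))
        xo, yo, zo = out_data.shape[2:]

        def _bw(g):
            if self.bias.requires_grad:
                self.bias._accumulate(g.sum(axis=(0, 2, 3, 4)))
            if self.weight.requires_grad:
                gw = np.tensordot(g, win, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
                self.weight._accumulate(gw)  # (cout, cin, k, k, k)
            if x.requires_grad:
                gxp = np.zeros_like(xp)
                for kx in range(k):
                    for ky in range(k):
                        for kz in range(k):
                            contrib = np.tensordot(
                                g, self.weight.data[:, :, kx, ky, kz], axes=([1], [0])
                            )  # (b, xo, yo, zo, cin)
                            gxp[
                                :, :, kx : kx + s * xo : s,
                                ky : ky + s * yo : s, kz : kz + s * zo : s,
                            ] += np.moveaxis(contrib, 4, 1)
                sl = tuple(
                    [slice(None), slice(None)]
                    + [slice(p, p + dim) for dim in spatial]
                )
                x._accumulate(gxp[sl])

        out._backward = _bw
        return out


class GRUCell(Module):
    """Single gated recurrent unit step, batched: (B, in) x (B, h) -> (B, h)."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.hidden_size = hidden_size
        self.w_ih = Tensor(_glorot(rng, input_size, 3 * hidden_size), requires_grad=True)
        self.w_hh = Tensor(_glorot(rng, hidden_size, 3 * hidden_size), requires_grad=True)
        self.b_ih = Tensor(np.zeros(3 * hidden_size), requires_grad=True)
        self.b_hh = Tensor(np.zeros(3 * hidden_size), requires_grad=True)

    def forward(self, x: Tensor, h: Tensor) -> Tensor:
        H = self.hidden_size
        gi = as_tensor(x) @ self.w_ih + self.b_ih
        gh = as_tensor(h) @ self.w_hh + self.b_hh
        r = (gi[:, :H] + gh[:, :H]).sigmoid()
        z = (gi[:, H : 2 * H] + gh[:, H : 2 * H]).sigmoid()
        n = (gi[:, 2 * H :] + r * gh[:, 2 * H :]).tanh()
        return (Tensor(1.0) - z) * n + z * as_tensor(h)


class GRU(Module):
    """Stacked, optionally bidirectional GRU over (B, T, in) sequences."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator,
                 num_layers: int = 1, bidirectional: bool = False):
        super().__init__()
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        self.bidirectional = bidirectional
        self.cells_fw = []
        self.cells_bw = []
        in_size = input_size
        for _ in range(num_layers):
            self.cells_fw.append(GRUCell(in_size, hidden_size, rng))
            if bidirectional:
                self.cells_bw.append(GRUCell(in_size, hidden_size, rng))
            in_size = hidden_size * (2 if bidirectional else 1)

    def _run_direction(self, cell: GRUCell, steps: list[Tensor], reverse: bool):
        b = steps[0].shape[0]
        h = Tensor(np.zeros((b, cell.hidden_size)))
        order = reversed(steps) if reverse else steps
        outs = [h := cell(x_t, h) for x_t in order]
        return outs[::-1] if reverse else outs

    def forward(self, x: Tensor) -> Tensor:
        """Return the full state sequence, shape (B, T, h_out)."""
        x = as_tensor(x)
        b, t, _ = x.shape
        steps = [x[:, i, :] for i in range(t)]
        for layer in range(self.num_layers):
            fw = self._run_direction(self.cells_fw[layer], steps, reverse=False)
            if self.bidirectional:
                bw = self._run_direction(self.cells_bw[layer], steps, reverse=True)
                steps = [concat([f, bk], axis=1) for f, bk in zip(fw, bw)]
            else:
                steps = fw
        return stack(steps, axis=1)


class MLP(Module):
    """Dense stack with ReLU between layers (no trailing nonlinearity)."""

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator):
        super().__init__()
        self.layers = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]

    def forward(self, x: Tensor) -> Tensor:
        out = as_tensor(x)
        for i, layer in enumerate(self.layers):
            out = layer(out)
            if i < len(self.layers) - 1:
                out = out.relu()
        return out


class Adam:
    """Adam with decoupled per-tensor state."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                p.data = p.data * (1.0 - self.lr * self.weight_decay)
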