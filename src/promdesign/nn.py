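"""Minimal reverse-mode autodiff and neural-network layers on numpy.

The adversarial generator and the two-branch strength regressor need
1-D/2-D convolutions, (bidirectional) LSTM recurrence, dense heads and
Adam — all trained on CPU at modest problem sizes.  This module provides
exactly that surface: a :class:`Tensor` recording a tape of numpy
operations, reverse-mode :meth:`Tensor.backward`, a handful of layers,
and an :class:`Adam` optimizer with optional per-tensor freezing.

Correctness is established by finite-difference gradient checks in the
test suite; everything is deterministic given a seeded
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "Dense",
    "Conv1D",
    "Conv2D",
    "maxpool1d",
    "maxpool2d",
    "LSTM",
    "BiLSTM",
    "Adam",
    "mse_loss",
    "bce_loss",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape entry needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None, name=""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward
        self.name = name

    # ---- infrastructure -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _accum(self, grad: np.ndarray, owned: bool = False) -> None:
        # ``owned`` marks gradients freshly allocated by the caller: they can
        # be adopted without a defensive copy.
        if self.grad is None:
            if owned and grad.shape == self.data.shape:
                self.grad = grad
            elif grad.shape == self.data.shape:
                self.grad = np.array(grad)
            else:
                self.grad = np.zeros_like(self.data)
                self.grad += grad
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; recursion depth would exceed limits on RNN tapes
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = _unbroadcast(g, self.data.shape)
                self._accum(ga, owned=ga is not g)
            if other.requires_grad:
                gb = _unbroadcast(g, other.data.shape)
                other._accum(gb, owned=gb is not g)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape), owned=True)
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape), owned=True)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * (other ** -1.0)

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0), owned=True)

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape), owned=True)
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape), owned=True)

        out._backward = bw
        return out

    # ---- elementwise nonlinearities -------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * out.data, owned=True)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data, owned=True)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (1.0 - out.data**2), owned=True)
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * out.data * (1.0 - out.data), owned=True
        )
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (self.data > 0), owned=True)
        return out

    # ---- reductions and shape ops ---------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        idx = np.expand_dims(self.data.argmax(axis=axis), axis)
        mx = np.take_along_axis(self.data, idx, axis)
        out = Tensor(mx if keepdims else np.squeeze(mx, axis), parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(self.data)  # ties route to the first maximum
            np.put_along_axis(full, idx, g, axis)
            self._accum(full, owned=True)

        out._backward = bw
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g.reshape(self.data.shape)
        )
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full, owned=True)

        out._backward = bw
        return out

    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class: subclasses register named parameter tensors."""

    def __init__(self, name: str):
        self.name = name
        self.params: dict[str, Tensor] = {}

    def _param(self, key: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True, name=f"{self.name}.{key}")
        self.params[key] = t
        return t


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = "dense"):
        super().__init__(name)
        self.W = self._param("W", _glorot(rng, n_in, n_out, (n_in, n_out)))
        self.b = self._param("b", np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Conv1D(Layer):
    """Valid-mode 1-D convolution over (batch, time, channels) input."""

    def __init__(self, c_in: int, filters: int, kernel: int, rng, name: str = "conv1d"):
        super().__init__(name)
        self.kernel = kernel
        self.W = self._param(
            "W", _glorot(rng, kernel * c_in, filters, (kernel * c_in, filters))
        )
        self.b = self._param("b", np.zeros(filters))

    def __call__(self, x: Tensor) -> Tensor:
        B, T, C = x.shape
        t_out = T - self.kernel + 1
        idx = np.arange(t_out)[:, None] + np.arange(self.kernel)[None, :]
        cols = x[:, idx, :]  # (B, t_out, kernel, C) via tape-recorded fancy indexing
        cols = cols.reshape(B * t_out, self.kernel * C)  # 2-D GEMM is much faster
        out = cols @ self.W + self.b
        return out.reshape(B, t_out, -1)


class Conv2D(Layer):
    """Valid-mode 2-D convolution over (batch, H, W, channels) input."""

    def __init__(self, c_in: int, filters: int, kernel: int, rng, name: str = "conv2d"):
        super().__init__(name)
        self.kernel = kernel
        k2 = kernel * kernel
        self.W = self._param("W", _glorot(rng, k2 * c_in, filters, (k2 * c_in, filters)))
        self.b = self._param("b", np.zeros(filters))

    def __call__(self, x: Tensor) -> Tensor:
        B, H, W, C = x.shape
        k = self.kernel
        h_out, w_out = H - k + 1, W - k + 1
        ri = (np.arange(h_out)[:, None] + np.arange(k)[None, :]).reshape(h_out, 1, k, 1)
        ci = (np.arange(w_out)[:, None] + np.arange(k)[None, :]).reshape(1, w_out, 1, k)
        rows = np.broadcast_to(ri, (h_out, w_out, k, k))
        cols = np.broadcast_to(ci, (h_out, w_out, k, k))
        patches = x[:, rows, cols, :]  # (B, h_out, w_out, k, k, C)
        patches = patches.reshape(B * h_out * w_out, k * k * C)
        out = patches @ self.W + self.b
        return out.reshape(B, h_out, w_out, -1)


def maxpool1d(x: Tensor, width: int = 2) -> Tensor:
    B, T, C = x.shape
    t_out = T // width
    x = x[:, : t_out * width, :] if T % width else x
    return x.reshape(B, t_out, width, C).max(axis=2)


def maxpool2d(x: Tensor, width: int = 2) -> Tensor:
    B, H, W, C = x.shape
    h_out, w_out = H // width, W // width
    x = x[:, : h_out * width, : w_out * width, :] if (H % width or W % width) else x
    x = x.reshape(B, h_out, width, w_out, width, C)
    return x.max(axis=4).max(axis=2)


class LSTM(Layer):
    """Single-layer LSTM; returns the final hidden state (batch, hidden).

    Gate order in the fused weight matrices is (input, forget, cell, output);
    the forget-gate bias is initialized to 1, the standard stabilizer.
    """

    def __init__(self, n_in: int, hidden: int, rng, name: str = "lstm"):
        super().__init__(name)
        self.hidden = hidden
        H = hidden
        self.W = self._param("W", _glorot(rng, n_in, 4 * H, (n_in, 4 * H)))
        self.U = self._param("U", _glorot(rng, H, 4 * H, (H, 4 * H)))
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0
        self.b = self._param("b", b)

    def __call__(self, x: Tensor, return_sequence: bool = False):
        B, T, _ = x.shape
        H = self.hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outputs = []
        for t in range(T):
            z = x[:, t, :] @ self.W + h @ self.U + self.b
            i = z[:, 0 * H : 1 * H].sigmoid()
            f = z[:, 1 * H : 2 * H].sigmoid()
            g = z[:, 2 * H : 3 * H].tanh()
            o = z[:, 3 * H : 4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            if return_sequence:
                outputs.append(h)
        if return_sequence:
            return outputs
        return h


class BiLSTM(Layer):
    """Forward and reversed LSTM passes; concatenated final hidden states."""

    def __init__(self, n_in: int, hidden: int, rng, name: str = "bilstm"):
        super().__init__(name)
        self.fwd = LSTM(n_in, hidden, rng, name=f"{name}.fwd")
        self.bwd = LSTM(n_in, hidden, rng, name=f"{name}.bwd")
        for prefix, layer in (("fwd", self.fwd), ("bwd", self.bwd)):
            for key, tensor in layer.params.items():
                self.params[f"{prefix}_{key}"] = tensor

    def __call__(self, x: Tensor) -> Tensor:
        T = x.shape[1]
        rev = x[:, np.arange(T - 1, -1, -1), :]
        return concat([self.fwd(x), self.bwd(rev)], axis=1)


# ---------------------------------------------------------------------------
# losses and optimizer
# ---------------------------------------------------------------------------


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(target)
    return (diff * diff).mean()


def bce_loss(prob: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Binary cross-entropy on probabilities in (0, 1)."""
    t = Tensor(np.asarray(target, dtype=np.float64))
    p = prob * (1.0 - 2.0 * eps) + eps  # clamp away from {0, 1}
    return -(t * p.log() + (1.0 - t) * (1.0 - p).log()).mean()


class Adam:
    """Adam with optional frozen (locked) parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self._scratch = [np.empty_like(p.data) for p in params]
        self.t = 0
        self.frozen: set[int] = set()

    def freeze(self, indices) -> None:
        self.frozen = set(int(i) for i in indices)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if i in self.frozen or p.grad is None:
                continue
            g = p.grad
            m, v, s = self.m[i], self.v[i], self._scratch[i]
            m *= self.beta1
            np.multiply(g, 1 - self.beta1, out=s)
            m += s
            v *= self.beta2
            np.square(g, out=s)
            s *= 1 - self.beta2
            v += s
            np.divide(v, b2t, out=s)
            np.sqrt(s, out=s)
            s += self.eps
            np.divide(m, s, out=s)
            s *= self.lr / b1t
            p.data -= s
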