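"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough machinery for recurrent encoders and fully connected heads:
tensors carry their data, a gradient slot, and a closure that propagates the
output gradient to the inputs.  ``Tensor.backward`` runs a topological sweep.
Shapes are ordinary 2-D batches ``(B, features)``; broadcasting is supported
for bias addition and elementwise products.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad = None
        self._prev = _prev
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def back():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))
        out._backward = back
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def back():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))
        out._backward = back
        return out

    def __neg__(self):
        return self * Tensor(-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    __radd__ = __add__
    __rmul__ = __mul__

    def __matmul__(self, other):
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def back():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)
        out._backward = back
        return out

    # -- nonlinearities -----------------------------------------------------

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, self.requires_grad, (self,))

        def back():
            if self.requires_grad:
                self._accum(out.grad * y * (1.0 - y))
        out._backward = back
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def back():
            if self.requires_grad:
                self._accum(out.grad * (1.0 - y * y))
        out._backward = back
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))

        def back():
            if self.requires_grad:
                self._accum(out.grad * mask)
        out._backward = back
        return out

    # -- shape ops ----------------------------------------------------------

    def cols(self, a: int, b: int):
        """Column slice ``[:, a:b]``."""
        out = Tensor(self.data[:, a:b], self.requires_grad, (self,))

        def back():
            if self.requires_grad:
                if self.grad is None:
                    self.grad = np.zeros_like(self.data)
                self.grad[:, a:b] += out.grad
        out._backward = back
        return out

    def sum(self):
        out = Tensor(self.data.sum(), self.requires_grad, (self,))

        def back():
            if self.requires_grad:
                self._accum(np.full_like(self.data, out.grad))
        out._backward = back
        return out

    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean(), self.requires_grad, (self,))

        def back():
            if self.requires_grad:
                self._accum(np.full_like(self.data, out.grad / n))
        out._backward = back
        return out

    # -- graph traversal ----------------------------------------------------

    def backward(self):
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.requires_grad:
                node._backward()


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def back():
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out.grad.ndim
                idx[axis] = slice(a, b)
                t._accum(out.grad[tuple(idx)])
    out._backward = back
    return out


def lstm_seq(rest: np.ndarray, W: Tensor, b: Tensor, bg: Tensor | None = None,
             h0: Tensor | None = None, c0: Tensor | None = None) -> Tensor:
    """Run an LSTM over a whole sequence as a single graph node.

    ``rest`` is a constant input block ``(B, T, C)``; ``bg`` is an optional
    differentiable first channel ``(B, T)`` (the glucose channel inside a
    residual stack).  ``W`` has shape ``(C[+1]+H, 4H)`` with gate order
    i, f, g, o; ``h0``/``c0`` are optional initial states ``(B, H)``.
    Returns the final hidden state ``(B, H)``; the backward pass is
    hand-written backpropagation through time, which keeps the graph small
    enough for 70+-step sequences to be cheap.
    """
    B, T = rest.shape[0], rest.shape[1]
    H = W.data.shape[1] // 4
    if bg is not None:
        x = np.concatenate([bg.data[:, :, None], rest], axis=2)
    else:
        x = rest
    D = x.shape[2]
    h = h0.data.copy() if h0 is not None else np.zeros((B, H))
    c = c0.data.copy() if c0 is not None else np.zeros((B, H))
    # one input-projection GEMM for all steps
    zx = x.reshape(B * T, D) @ W.data[:D] + b.data
    zx = zx.reshape(B, T, 4 * H)
    Wh = W.data[D:]
    gates_i = np.empty((B, T, H)); gates_f = np.empty((B, T, H))
    gates_g = np.empty((B, T, H)); gates_o = np.empty((B, T, H))
    cs = np.empty((B, T, H)); tanh_cs = np.empty((B, T, H))
    hs_prev = np.empty((B, T, H)); cs_prev = np.empty((B, T, H))
    for t in range(T):
        hs_prev[:, t] = h
        cs_prev[:, t] = c
        z = zx[:, t] + h @ Wh
        i = 1.0 / (1.0 + np.exp(-z[:, :H]))
        f = 1.0 / (1.0 + np.exp(-z[:, H:2 * H]))
        g = np.tanh(z[:, 2 * H:3 * H])
        o = 1.0 / (1.0 + np.exp(-z[:, 3 * H:]))
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        gates_i[:, t], gates_f[:, t], gates_g[:, t], gates_o[:, t] = i, f, g, o
        cs[:, t], tanh_cs[:, t] = c, tc
    parents = tuple(p for p in (W, b, bg, h0, c0) if p is not None)
    out = Tensor(h, any(p.requires_grad for p in parents), parents)

    def back():
        dh = out.grad
        dc = np.zeros((B, H))
        dz_all = np.empty((B, T, 4 * H))
        for t in range(T - 1, -1, -1):
            i, f = gates_i[:, t], gates_f[:, t]
            g, o = gates_g[:, t], gates_o[:, t]
            tc = tanh_cs[:, t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * cs_prev[:, t]
            dg = dc * i
            dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g * g), do * o * (1 - o)], axis=1)
            dz_all[:, t] = dz
            dh = dz @ Wh.T
            dc = dc * f
        dz_flat = dz_all.reshape(B * T, 4 * H)
        if W.requires_grad:
            dW = np.empty_like(W.data)
            dW[:D] = x.reshape(B * T, D).T @ dz_flat
            dW[D:] = hs_prev.reshape(B * T, H).T @ dz_flat
            W._accum(dW)
        if b.requires_grad:
            b._accum(dz_flat.sum(axis=0))
        if bg is not None and bg.requires_grad:
            dx = dz_flat @ W.data[:D].T
            bg._accum(dx.reshape(B, T, D)[:, :, 0])
        if h0 is not None and h0.requires_grad:
            h0._accum(dh)
        if c0 is not None and c0.requires_grad:
            c0._accum(dc)
    out._backward = back
    return out


def mse(a: Tensor, b: Tensor) -> Tensor:
    d = a - b
    return (d * d).mean()


def parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Adam:
    """Standard Adam over a name -> Tensor parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * p.grad
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * p.grad ** 2
            p.data -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
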