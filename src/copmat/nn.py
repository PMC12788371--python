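"""A compact reverse-mode autodiff engine and NN layers over numpy.

Provides exactly the operator set the CoP regressors need: dense and
2D strided convolutions (im2col), ReLU / sigmoid / tanh, concatenation,
global average pooling, (bi)directional LSTM layers, mean-squared-error
loss, Adam, and a step-decay learning-rate schedule.  Everything is
seeded and single-threaded-deterministic.
"""

from __future__ import annotations

import numpy as np

#: computation dtype of the engine; float32 keeps BLAS fast and memory low
DTYPE = np.float32


class Tensor:
    """An ndarray node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()
        # break closure cycles so the graph frees by reference counting
        for t in topo:
            t._backward = None
            t._parents = ()

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return add(self, mul_scalar(other, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Reduce gradient ``g`` back to the broadcast-source ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# primitive ops

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward():
        if a.requires_grad:
            a._accum(_unbroadcast(out.grad, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(out.grad, b.shape))

    out = _make(out_data, (a, b), backward)
    return out


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward():
        if a.requires_grad:
            a._accum(_unbroadcast(out.grad * b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(out.grad * a.data, b.shape))

    out = _make(out_data, (a, b), backward)
    return out


def mul_scalar(a, s: float) -> Tensor:
    a = _as_tensor(a)

    def backward():
        if a.requires_grad:
            a._accum(out.grad * s)

    out = _make(a.data * s, (a,), backward)
    return out


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def backward():
        if a.requires_grad:
            ga = out.grad @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ out.grad
            b._accum(_unbroadcast(gb, b.shape))

    out = _make(out_data, (a, b), backward)
    return out


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0

    def backward():
        if a.requires_grad:
            a._accum(out.grad * mask)

    out = _make(a.data * mask, (a,), backward)
    return out


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    with np.errstate(over="ignore"):  # saturates cleanly in float32
        s = 1.0 / (1.0 + np.exp(-a.data))

    def backward():
        if a.requires_grad:
            a._accum(out.grad * s * (1 - s))

    out = _make(s, (a,), backward)
    return out


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    th = np.tanh(a.data)

    def backward():
        if a.requires_grad:
            a._accum(out.grad * (1 - th * th))

    out = _make(th, (a,), backward)
    return out


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    old = a.shape

    def backward():
        if a.requires_grad:
            a._accum(out.grad.reshape(old))

    out = _make(a.data.reshape(shape), (a,), backward)
    return out


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)

    def backward():
        start = 0
        for t, n in zip(tensors, sizes):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(start, start + n)
                t._accum(out.grad[tuple(sl)])
            start += n

    out = _make(out_data, tensors, backward)
    return out


def slice_axis(a, axis: int, start: int, stop: int) -> Tensor:
    a = _as_tensor(a)
    sl = [slice(None)] * a.data.ndim
    sl[axis] = slice(start, stop)
    sl = tuple(sl)

    def backward():
        if a.requires_grad:
            g = np.zeros_like(a.data)
            g[sl] = out.grad
            a._accum(g)

    out = _make(a.data[sl], (a,), backward)
    return out


def index_time(a, t: int) -> Tensor:
    """Select time step ``t`` of a (B, T, F) tensor -> (B, F)."""
    a = _as_tensor(a)

    def backward():
        if a.requires_grad:
            g = np.zeros_like(a.data)
            g[:, t] = out.grad
            a._accum(g)

    out = _make(a.data[:, t], (a,), backward)
    return out


def stack_time(tensors) -> Tensor:
    """Stack T tensors of (B, F) into (B, T, F)."""
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=1)

    def backward():
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(out.grad[:, i])

    out = _make(out_data, tensors, backward)
    return out


def mean_axes(a, axes) -> Tensor:
    a = _as_tensor(a)
    axes = tuple(axes)
    n = int(np.prod([a.shape[ax] for ax in axes]))
    out_data = a.data.mean(axis=axes)

    def backward():
        if a.requires_grad:
            g = np.expand_dims(out.grad, axes)
            a._accum(np.broadcast_to(g, a.shape) / n)

    out = _make(out_data, (a,), backward)
    return out


def mse_loss(pred, target) -> Tensor:
    pred = _as_tensor(pred)
    diff = pred.data.astype(np.float64) - np.asarray(target, dtype=np.float64)
    n = diff.size

    def backward():
        if pred.requires_grad:
            pred._accum((out.grad * 2.0 * diff / n).astype(DTYPE))

    out = _make(np.array(np.mean(diff**2)), (pred,), backward)
    return out


# ---------------------------------------------------------------------------
# convolution via im2col

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """Lay out conv patches as one (c*kh*kw, n*ho*wo) GEMM operand."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
    )
    cols = np.ascontiguousarray(cols.transpose(1, 2, 3, 0, 4, 5))
    return cols.reshape(c * kh * kw, n * ho * wo), ho, wo


def _col2im(gcols: np.ndarray, x_shape, kh, kw, stride, pad, ho, wo):
    """Scatter-add column gradients back onto the (padded) input."""
    n, c, h, w = x_shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=gcols.dtype)
    blocks = gcols.reshape(c, kh, kw, n, ho, wo)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                blocks[:, i, j].transpose(1, 0, 2, 3)
    return xp[:, :, pad:pad + h, pad:pad + w] if pad else xp


def conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0) -> Tensor:
    """2D convolution: x (N, Cin, H, W), weight (Cout, Cin, kh, kw)."""
    x, weight = _as_tensor(x), _as_tensor(weight)
    n, cin, h, w = x.shape
    cout, _, kh, kw = weight.shape
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    wmat = weight.data.reshape(cout, -1)
    out_flat = wmat @ cols  # (cout, n*ho*wo)
    out_data = np.ascontiguousarray(
        out_flat.reshape(cout, n, ho, wo).transpose(1, 0, 2, 3)
    )
    parents = [x, weight]
    if bias is not None:
        bias = _as_tensor(bias)
        out_data += bias.data.reshape(1, cout, 1, 1)
        parents.append(bias)

    def backward():
        g = np.ascontiguousarray(out.grad.transpose(1, 0, 2, 3)).reshape(cout, -1)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=1))
        if weight.requires_grad:
            weight._accum((g @ cols.T).reshape(weight.shape))
        if x.requires_grad:
            gcols = wmat.T @ g
            x._accum(_col2im(gcols, x.data.shape, kh, kw, stride, padding, ho, wo))

    out = _make(out_data, parents, backward)
    return out


# ---------------------------------------------------------------------------
# layers

class Module:
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

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(n_in)
        self.weight = Tensor(rng.uniform(-bound, bound, (n_in, n_out)), True)
        self.bias = Tensor(rng.uniform(-bound, bound, n_out), True)

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.weight), self.bias)


class Conv2d(Module):
    def __init__(self, cin, cout, k, stride, padding, rng: np.random.Generator):
        fan_in = cin * k * k
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Tensor(rng.uniform(-bound, bound, (cout, cin, k, k)), True)
        self.bias = Tensor(rng.uniform(-bound, bound, cout), True)
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class LSTM(Module):
    """Single-layer LSTM over (B, T, F); returns (B, T, H)."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator,
                 reverse: bool = False):
        bound = 1.0 / np.sqrt(hidden)
        self.wx = Tensor(rng.uniform(-bound, bound, (n_in, 4 * hidden)), True)
        self.wh = Tensor(rng.uniform(-bound, bound, (hidden, 4 * hidden)), True)
        self.b = Tensor(rng.uniform(-bound, bound, 4 * hidden), True)
        self.hidden = hidden
        self.reverse = reverse

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        H = self.hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        steps = range(T - 1, -1, -1) if self.reverse else range(T)
        outs: list[Tensor | None] = [None] * T
        for t in steps:
            xt = index_time(x, t)
            gates = add(add(matmul(xt, self.wx), matmul(h, self.wh)), self.b)
            i = sigmoid(slice_axis(gates, 1, 0, H))
            f = sigmoid(slice_axis(gates, 1, H, 2 * H))
            g = tanh(slice_axis(gates, 1, 2 * H, 3 * H))
            o = sigmoid(slice_axis(gates, 1, 3 * H, 4 * H))
            c = add(mul(f, c), mul(i, g))
            h = mul(o, tanh(c))
            outs[t] = h
        return stack_time(outs)


class BiLSTM(Module):
    """Bidirectional LSTM: forward and backward passes concatenated (2H)."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.fwd = LSTM(n_in, hidden, rng)
        self.bwd = LSTM(n_in, hidden, rng, reverse=True)

    def __call__(self, x: Tensor) -> Tensor:
        return concat([self.fwd(x), self.bwd(x)], axis=-1)


# ---------------------------------------------------------------------------
# optimization

class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class StepLR:
    """Multiply the optimizer's learning rate by ``gamma`` every
    ``step_size`` epochs."""

    def __init__(self, optimizer: Adam, step_size: int, gamma: float):
        self.optimizer = optimizer
        self.step_size = step_size
        self.gamma = gamma
        self.epoch = 0
        self.base_lr = optimizer.lr

    def step(self):
        self.epoch += 1
        self.optimizer.lr = self.base_lr * self.gamma ** (self.epoch // self.step_size)

    @property
    def lr(self) -> float:
        return self.optimizer.lr
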