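"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides the tensor type, the layer primitives (dense, 2-D convolution with
dilation, group/layer normalisation, pooling, nearest-neighbour upsampling,
multi-head-attention building blocks), the Adam optimiser and the cosine
annealing learning-rate schedule used by both the segmentation networks and
the transformer classifier.  Gradients of every primitive are checked against
central finite differences in the test suite.

Arrays are float64 throughout: the networks here are deliberately small, so
numerical robustness is worth more than the memory savings of float32.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "Conv2d",
    "GroupNorm",
    "LayerNorm",
    "Adam",
    "cosine_annealing_lr",
    "concat",
    "stack_bc",
    "softmax",
    "relu",
    "sigmoid",
]


class Tensor:
    """Node in the computation graph: a value, its gradient, and a backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _init_grad(self):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
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
            if node._backward is not None:
                node._backward()
        # break the closure reference cycles so large buffers free promptly
        for node in topo:
            node._backward = None
            node._prev = ()

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = _node(self.data + other.data, (self, other))

        def bwd():
            if self.requires_grad:
                self._init_grad()
                self.grad += _unbroadcast(out.grad, self.data.shape)
            if other.requires_grad:
                other._init_grad()
                other.grad += _unbroadcast(out.grad, other.data.shape)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _node(self.data * other.data, (self, other))

        def bwd():
            if self.requires_grad:
                self._init_grad()
                self.grad += _unbroadcast(out.grad * other.data, self.data.shape)
            if other.requires_grad:
                other._init_grad()
                other.grad += _unbroadcast(out.grad * self.data, other.data.shape)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out = _node(self.data ** p, (self,))

        def bwd():
            if self.requires_grad:
                self._init_grad()
                self.grad += out.grad * p * self.data ** (p - 1.0)

        out._backward = bwd
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = _node(self.data @ other.data, (self, other))

        def bwd():
            if self.requires_grad:
                self._init_grad()
                g = out.grad @ np.swapaxes(other.data, -1, -2)
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other._init_grad()
                g = np.swapaxes(self.data, -1, -2) @ out.grad
                other.grad += _unbroadcast(g, other.data.shape)

        out._backward = bwd
        return out

    __matmul__ = matmul

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _node(self.data.reshape(shape), (self,))

        def bwd():
            if self.requires_grad:
                self._init_grad()
                self.grad += out.grad.reshape(self.data.shape)

        out._backward = bwd
        return out

    def transpose(self, *axes) -> "Tensor":
        out = _node(self.data.transpose(axes), (self,))
        inv = np.argsort(axes)

        def bwd():
            if self.requires_grad:
                self._init_grad()
                self.grad += out.grad.transpose(inv)

        out._backward = bwd
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = _node(self.data[idx], (self,))

        def bwd():
            if self.requires_grad:
                self._init_grad()
                np.add.at(self.grad, idx, out.grad)

        out._backward = bwd
        return out

    # -- reductions & elementwise -----------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd():
            if self.requires_grad:
                self._init_grad()
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self.grad += np.broadcast_to(g, self.data.shape)

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def exp(self) -> "Tensor":
        out = _node(np.exp(self.data), (self,))

        def bwd():
            if self.requires_grad:
                self._init_grad()
                self.grad += out.grad * out.data

        out._backward = bwd
        return out

    def log(self) -> "Tensor":
        out = _node(np.log(self.data), (self,))

        def bwd():
            if self.requires_grad:
                self._init_grad()
                self.grad += out.grad / self.data

        out._backward = bwd
        return out

    def relu(self) -> "Tensor":
        out = _node(np.maximum(self.data, 0.0), (self,))

        def bwd():
            if self.requires_grad:
                self._init_grad()
                self.grad += out.grad * (self.data > 0.0)

        out._backward = bwd
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = _node(s, (self,))

        def bwd():
            if self.requires_grad:
                self._init_grad()
                self.grad += out.grad * s * (1.0 - s)

        out._backward = bwd
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = _node(t, (self,))

        def bwd():
            if self.requires_grad:
                self._init_grad()
                self.grad += out.grad * (1.0 - t * t)

        out._backward = bwd
        return out


class Parameter(Tensor):
    """A tensor that an optimiser updates."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, prev: tuple) -> Tensor:
    out = Tensor(data)
    out._prev = tuple(p for p in prev if isinstance(p, Tensor))
    out.requires_grad = any(p.requires_grad for p in out._prev)
    if not out.requires_grad:
        out._prev = ()
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to the operand's shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# Functional ops
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    return x.relu()


def sigmoid(x: Tensor) -> Tensor:
    return x.sigmoid()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._init_grad()
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t.grad += out.grad[tuple(sl)]

    out._backward = bwd
    return out


def stack_bc(x: Tensor, repeats: int, axis: int) -> Tensor:
    """Broadcast-repeat a size-1 axis (used to tile a learned token over a batch)."""
    reps = [1] * x.ndim
    reps[axis] = repeats
    out = _node(np.tile(x.data, reps), (x,))

    def bwd():
        if x.requires_grad:
            x._init_grad()
            x.grad += out.grad.sum(axis=axis, keepdims=True)

    out._backward = bwd
    return out


# -- convolution -----------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, pad: int, dilation: int) -> np.ndarray:
    """(B,C,H,W) -> (B, H, W, C*kh*kw) patches, stride 1, zero padding."""
    b, c, h, w = x.shape
    eff_kh = (kh - 1) * dilation + 1
    eff_kw = (kw - 1) * dilation + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = h + 2 * pad - eff_kh + 1
    ow = w + 2 * pad - eff_kw + 1
    s0, s1, s2, s3 = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp,
        shape=(b, c, oh, ow, kh, kw),
        strides=(s0, s1, s2, s3, s2 * dilation, s3 * dilation),
        writeable=False,
    )
    return np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5)).reshape(
        b, oh, ow, c * kh * kw
    )


def _col2im(cols: np.ndarray, x_shape: tuple, kh: int, kw: int, pad: int,
            dilation: int) -> np.ndarray:
    """Adjoint of _im2col."""
    b, c, h, w = x_shape
    oh, ow = cols.shape[1], cols.shape[2]
    xp = np.zeros((b, c, h + 2 * pad, w + 2 * pad))
    cols = cols.reshape(b, oh, ow, c, kh, kw)
    for i in range(kh):
        di = i * dilation
        for j in range(kw):
            dj = j * dilation
            xp[:, :, di:di + oh, dj:dj + ow] += cols[:, :, :, :, i, j].transpose(
                0, 3, 1, 2
            )
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
           padding: int | None = None, dilation: int = 1) -> Tensor:
    """Stride-1 'same' convolution.  weight: (Cout, Cin, kh, kw)."""
    cout, cin, kh, kw = weight.data.shape
    if padding is None:
        padding = ((kh - 1) * dilation) // 2
    cols = _im2col(x.data, kh, kw, padding, dilation)  # (B,OH,OW,Cin*kh*kw)
    wmat = weight.data.reshape(cout, -1)
    y = cols @ wmat.T  # (B,OH,OW,Cout)
    if bias is not None:
        y = y + bias.data
    out = _node(np.ascontiguousarray(y.transpose(0, 3, 1, 2)),
                (x, weight) + ((bias,) if bias is not None else ()))

    def bwd():
        g = out.grad.transpose(0, 2, 3, 1)  # (B,OH,OW,Cout)
        if weight.requires_grad:
            weight._init_grad()
            gw = np.tensordot(g, cols, axes=([0, 1, 2], [0, 1, 2]))
            weight.grad += gw.reshape(weight.data.shape)
        if bias is not None and bias.requires_grad:
            bias._init_grad()
            bias.grad += g.sum(axis=(0, 1, 2))
        if x.requires_grad:
            x._init_grad()
            gcols = g @ wmat  # (B,OH,OW,Cin*kh*kw)
            x.grad += _col2im(gcols, x.data.shape, kh, kw, padding, dilation)

    out._backward = bwd
    return out


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    b, c, h, w = x.data.shape
    oh, ow = h // k, w // k
    xr = x.data[:, :, :oh * k, :ow * k].reshape(b, c, oh, k, ow, k)
    patches = xr.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, oh, ow, k * k)
    idx = patches.argmax(axis=-1)
    out = _node(np.take_along_axis(patches, idx[..., None], axis=-1)[..., 0], (x,))

    def bwd():
        if x.requires_grad:
            x._init_grad()
            gp = np.zeros((b, c, oh, ow, k * k))
            np.put_along_axis(gp, idx[..., None], out.grad[..., None], axis=-1)
            gp = gp.reshape(b, c, oh, ow, k, k).transpose(0, 1, 2, 4, 3, 5)
            x.grad[:, :, :oh * k, :ow * k] += gp.reshape(b, c, oh * k, ow * k)

    out._backward = bwd
    return out


def avg_pool_global(x: Tensor) -> Tensor:
    """(B,C,H,W) -> (B,C,1,1) mean over the spatial axes."""
    return x.mean(axis=(2, 3), keepdims=True)


def upsample_nearest2x(x: Tensor) -> Tensor:
    out = _node(x.data.repeat(2, axis=2).repeat(2, axis=3), (x,))

    def bwd():
        if x.requires_grad:
            x._init_grad()
            b, c, h, w = x.data.shape
            g = out.grad.reshape(b, c, h, 2, w, 2).sum(axis=(3, 5))
            x.grad += g

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Module:
    """Base class: tracks parameters recursively, supports train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        stack: list = [self]
        while stack:
            obj = stack.pop()
            for v in vars(obj).values():
                if isinstance(v, Parameter) and id(v) not in seen:
                    seen.add(id(v))
                    params.append(v)
                elif isinstance(v, Module):
                    stack.append(v)
                elif isinstance(v, (list, tuple)):
                    stack.extend(m for m in v if isinstance(m, Module))
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self):
        self._set_mode(True)

    def eval(self):
        self._set_mode(False)

    def _set_mode(self, flag: bool):
        self.training = flag
        for v in vars(self).values():
            if isinstance(v, Module):
                v._set_mode(flag)
            elif isinstance(v, (list, tuple)):
                for m in v:
                    if isinstance(m, Module):
                        m._set_mode(flag)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = state[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data[...] = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        scale = math.sqrt(2.0 / n_in)
        self.weight = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 dilation: int = 1, bias: bool = True):
        super().__init__()
        scale = math.sqrt(2.0 / (cin * k * k))
        self.weight = Parameter(rng.normal(0.0, scale, size=(cout, cin, k, k)))
        self.bias = Parameter(np.zeros(cout)) if bias else None
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, dilation=self.dilation)


class GroupNorm(Module):
    """Group normalisation over (C/G,H,W) groups; batch-size independent."""

    def __init__(self, channels: int, groups: int = 4, eps: float = 1e-5):
        super().__init__()
        self.groups = min(groups, channels)
        while channels % self.groups:
            self.groups -= 1
        self.eps = eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.data.shape
        g = self.groups
        xg = x.reshape(b, g, (c // g) * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=2, keepdims=True)
        xn = xc * (var + self.eps) ** -0.5
        xn = xn.reshape(b, c, h, w)
        return xn * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.gamma + self.beta


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


# ---------------------------------------------------------------------------
# Optimiser & schedule
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def cosine_annealing_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    """lr(0) = base_lr, lr(total_epochs - 1) ~ 0; half-cosine in between."""
    if total_epochs <= 1:
        return base_lr
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * epoch / (total_epochs - 1)))
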