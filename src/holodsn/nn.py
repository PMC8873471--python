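"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the tensor backend for the descattering networks: a small, explicit
set of differentiable operations (3D/2D convolution, ceil-mode max pooling,
nearest-neighbor upsampling, instance normalization, dense layers, softmax,
sigmoid/ReLU, binary cross-entropy) sufficient to express and train the
expert V-nets, the gating network, and their dynamic synthesis on a CPU.

Conventions: single-sample tensors, channels first — volumes are
(C, D, H, W), images (C, H, W), vectors (n,). All ops are deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "constant", "parameter",
    "add", "mul", "matmul", "relu", "sigmoid", "softmax_vec", "index",
    "tsum", "conv3d", "conv2d", "maxpool3d", "maxpool2d",
    "upsample_nearest3d", "concat", "instance_norm", "spatial_mean", "flatten",
    "linear", "bce",
]


class Tensor:
    """An ndarray node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.shape != ():
            raise ValueError("backward() requires a scalar tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.array(1.0)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else constant(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient over broadcast dimensions back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


# -- elementwise and linear algebra -----------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return Tensor(out_data, parents=(a, b), backward=backward)


def tsum(a) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.full(a.shape, g))

    return Tensor(a.data.sum(), parents=(a,), backward=backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return Tensor(a.data * mask, parents=(a,), backward=backward)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * s * (1.0 - s))

    return Tensor(s, parents=(a,), backward=backward)


def softmax_vec(a) -> Tensor:
    """Softmax of a 1D vector."""
    a = _as_tensor(a)
    shifted = a.data - a.data.max()
    e = np.exp(shifted)
    s = e / e.sum()

    def backward(g):
        if a.requires_grad:
            a._accumulate(s * (g - np.dot(g, s)))

    return Tensor(s, parents=(a,), backward=backward)


def index(a, i: int) -> Tensor:
    """Scalar element a[i] of a 1D tensor."""
    a = _as_tensor(a)

    def backward(g):
        if a.requires_grad:
            grad = np.zeros(a.shape)
            grad[i] = g
            a._accumulate(grad)

    return Tensor(a.data[i], parents=(a,), backward=backward)


def linear(x, weight, bias) -> Tensor:
    """Dense layer: weight (out, in) @ x (in,) + bias (out,)."""
    x, weight, bias = _as_tensor(x), _as_tensor(weight), _as_tensor(bias)
    out_data = weight.data @ x.data + bias.data

    def backward(g):
        if weight.requires_grad:
            weight._accumulate(np.outer(g, x.data))
        if bias.requires_grad:
            bias._accumulate(g)
        if x.requires_grad:
            x._accumulate(weight.data.T @ g)

    return Tensor(out_data, parents=(x, weight, bias), backward=backward)


# -- convolutions ------------------------------------------------------------

def conv3d(x, weight, bias) -> Tensor:
    """Same-padding, stride-1 3D convolution.

    x: (Cin, D, H, W); weight: (Cout, Cin, kd, kh, kw) with odd kernel sizes;
    bias: (Cout,). Implemented as a shift-and-accumulate over kernel offsets.
    """
    x, weight, bias = _as_tensor(x), _as_tensor(weight), _as_tensor(bias)
    cin, d, h, w = x.shape
    cout, cin_w, kd, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, weight {cin_w}")
    pd, ph, pw = kd // 2, kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (pd, pd), (ph, ph), (pw, pw)))
    out_data = np.zeros((cout, d, h, w))
    for dz in range(kd):
        for dy in range(kh):
            for dx in range(kw):
                patch = xp[:, dz:dz + d, dy:dy + h, dx:dx + w]
                out_data += np.tensordot(weight.data[:, :, dz, dy, dx], patch, axes=(1, 0))
    out_data += bias.data[:, None, None, None]

    def backward(g):
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(1, 2, 3)))
        if weight.requires_grad or x.requires_grad:
            gxp = np.zeros_like(xp) if x.requires_grad else None
            gw = np.zeros_like(weight.data) if weight.requires_grad else None
            for dz in range(kd):
                for dy in range(kh):
                    for dx in range(kw):
                        patch = xp[:, dz:dz + d, dy:dy + h, dx:dx + w]
                        if gw is not None:
                            gw[:, :, dz, dy, dx] = np.tensordot(
                                g, patch, axes=([1, 2, 3], [1, 2, 3]))
                        if gxp is not None:
                            gxp[:, dz:dz + d, dy:dy + h, dx:dx + w] += np.tensordot(
                                weight.data[:, :, dz, dy, dx].T, g, axes=(1, 0))
            if gw is not None:
                weight._accumulate(gw)
            if gxp is not None:
                x._accumulate(gxp[:, pd:pd + d, ph:ph + h, pw:pw + w])

    return Tensor(out_data, parents=(x, weight, bias), backward=backward)


def conv2d(x, weight, bias) -> Tensor:
    """Same-padding, stride-1 2D convolution: x (Cin, H, W), weight (Cout, Cin, kh, kw)."""
    x, weight, bias = _as_tensor(x), _as_tensor(weight), _as_tensor(bias)
    cin, h, w = x.shape
    cout, cin_w, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, weight {cin_w}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw)))
    out_data = np.zeros((cout, h, w))
    for dy in range(kh):
        for dx in range(kw):
            patch = xp[:, dy:dy + h, dx:dx + w]
            out_data += np.tensordot(weight.data[:, :, dy, dx], patch, axes=(1, 0))
    out_data += bias.data[:, None, None]

    def backward(g):
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(1, 2)))
        if weight.requires_grad or x.requires_grad:
            gxp = np.zeros_like(xp) if x.requires_grad else None
            gw = np.zeros_like(weight.data) if weight.requires_grad else None
            for dy in range(kh):
                for dx in range(kw):
                    patch = xp[:, dy:dy + h, dx:dx + w]
                    if gw is not None:
                        gw[:, :, dy, dx] = np.tensordot(g, patch, axes=([1, 2], [1, 2]))
                    if gxp is not None:
                        gxp[:, dy:dy + h, dx:dx + w] += np.tensordot(
                            weight.data[:, :, dy, dx].T, g, axes=(1, 0))
            if gw is not None:
                weight._accumulate(gw)
            if gxp is not None:
                x._accumulate(gxp[:, ph:ph + h, pw:pw + w])

    return Tensor(out_data, parents=(x, weight, bias), backward=backward)


# -- pooling and upsampling --------------------------------------------------

def _ceil_pad(size: int, k: int) -> int:
    return (-size) % k


def maxpool3d(x, kernel: tuple[int, int, int] = (2, 2, 2)) -> Tensor:
    """Ceil-mode max pooling: odd trailing sizes are padded with -inf."""
    x = _as_tensor(x)
    c, d, h, w = x.shape
    kd, kh, kw = kernel
    pads = (_ceil_pad(d, kd), _ceil_pad(h, kh), _ceil_pad(w, kw))
    xp = np.pad(x.data, ((0, 0), (0, pads[0]), (0, pads[1]), (0, pads[2])),
                constant_values=-np.inf)
    dd, hh, ww = xp.shape[1] // kd, xp.shape[2] // kh, xp.shape[3] // kw
    windows = xp.reshape(c, dd, kd, hh, kh, ww, kw).transpose(0, 1, 3, 5, 2, 4, 6)
    flat = windows.reshape(c, dd, hh, ww, kd * kh * kw)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if x.requires_grad:
            gflat = np.zeros_like(flat)
            np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
            gxp = gflat.reshape(c, dd, hh, ww, kd, kh, kw).transpose(
                0, 1, 4, 2, 5, 3, 6).reshape(xp.shape)
            x._accumulate(gxp[:, :d, :h, :w])

    return Tensor(out_data, parents=(x,), backward=backward)


def maxpool2d(x, kernel: tuple[int, int] = (2, 2)) -> Tensor:
    """Ceil-mode 2D max pooling on (C, H, W)."""
    x = _as_tensor(x)
    c, h, w = x.shape
    kh, kw = kernel
    pads = (_ceil_pad(h, kh), _ceil_pad(w, kw))
    xp = np.pad(x.data, ((0, 0), (0, pads[0]), (0, pads[1])), constant_values=-np.inf)
    hh, ww = xp.shape[1] // kh, xp.shape[2] // kw
    windows = xp.reshape(c, hh, kh, ww, kw).transpose(0, 1, 3, 2, 4)
    flat = windows.reshape(c, hh, ww, kh * kw)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if x.requires_grad:
            gflat = np.zeros_like(flat)
            np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
            gxp = gflat.reshape(c, hh, ww, kh, kw).transpose(0, 1, 3, 2, 4).reshape(xp.shape)
            x._accumulate(gxp[:, :h, :w])

    return Tensor(out_data, parents=(x,), backward=backward)


def upsample_nearest3d(x, target: tuple[int, int, int]) -> Tensor:
    """Nearest-neighbor 2x upsampling cropped to ``target`` spatial shape.

    Each target size must lie in [size, 2*size]; this inverts ceil-mode
    pooling (e.g. 7 -> 13).
    """
    x = _as_tensor(x)
    c, d, h, w = x.shape
    td, th, tw = target
    for s, t in zip((d, h, w), target):
        if not s <= t <= 2 * s:
            raise ValueError(f"target {target} incompatible with input {(d, h, w)}")
    up = x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)
    out_data = up[:, :td, :th, :tw]

    def backward(g):
        if x.requires_grad:
            gp = np.zeros((c, 2 * d, 2 * h, 2 * w))
            gp[:, :td, :th, :tw] = g
            gx = gp.reshape(c, d, 2, h, 2, w, 2).sum(axis=(2, 4, 6))
            x._accumulate(gx)

    return Tensor(out_data, parents=(x,), backward=backward)


def concat(a, b, axis: int = 0) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = np.concatenate([a.data, b.data], axis=axis)
    split = a.shape[axis]

    def backward(g):
        ga, gb = np.split(g, [split], axis=axis)
        if a.requires_grad:
            a._accumulate(ga)
        if b.requires_grad:
            b._accumulate(gb)

    return Tensor(out_data, parents=(a, b), backward=backward)


def instance_norm(x, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Per-channel standardization over spatial dims with learnable affine.

    x: (C, *spatial); gamma, beta: (C,). Statistics are recomputed per input
    (instance-style, no running averages).
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    axes = tuple(range(1, x.data.ndim))
    mean = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    sigma = np.sqrt(var + eps)
    xhat = (x.data - mean) / sigma
    bshape = (x.shape[0],) + (1,) * (x.data.ndim - 1)
    out_data = xhat * gamma.data.reshape(bshape) + beta.data.reshape(bshape)

    def backward(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if x.requires_grad:
            gs = g * gamma.data.reshape(bshape)
            m = np.prod([x.shape[a] for a in axes])
            gx = (gs - gs.mean(axis=axes, keepdims=True)
                  - xhat * (gs * xhat).mean(axis=axes, keepdims=True)) / sigma
            x._accumulate(gx)

    return Tensor(out_data, parents=(x, gamma, beta), backward=backward)


def flatten(x) -> Tensor:
    """Reshape to 1D, preserving order."""
    x = _as_tensor(x)
    shape = x.shape

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.reshape(shape))

    return Tensor(x.data.reshape(-1), parents=(x,), backward=backward)


def spatial_mean(x) -> Tensor:
    """Global average pool: (C, *spatial) -> (C,)."""
    x = _as_tensor(x)
    axes = tuple(range(1, x.data.ndim))
    m = np.prod([x.shape[a] for a in axes])

    def backward(g):
        if x.requires_grad:
            bshape = (x.shape[0],) + (1,) * (x.data.ndim - 1)
            x._accumulate(np.broadcast_to(g.reshape(bshape) / m, x.shape).copy())

    return Tensor(x.data.mean(axis=axes), parents=(x,), backward=backward)


def bce(pred, target, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy with prediction clamping.

    Predictions are clamped to [eps, 1-eps]; the gradient is zero where the
    clamp is active.
    """
    pred = _as_tensor(pred)
    target_data = np.asarray(_as_tensor(target).data)
    if pred.shape != target_data.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape}, target {target_data.shape}")
    p = np.clip(pred.data, eps, 1.0 - eps)
    n = p.size
    loss = -np.mean(target_data * np.log(p) + (1.0 - target_data) * np.log1p(-p))
    unclamped = (pred.data > eps) & (pred.data < 1.0 - eps)

    def backward(g):
        if pred.requires_grad:
            grad = (p - target_data) / (p * (1.0 - p) * n)
            pred._accumulate(g * grad * unclamped)

    return Tensor(loss, parents=(pred,), backward=backward)


# -- initialization ----------------------------------------------------------

def xavier_uniform(shape: tuple, rng: np.random.Generator,
                   fan_in: int | None = None, fan_out: int | None = None) -> np.ndarray:
    """Glorot uniform initialization U(-limit, limit), limit = sqrt(6/(fi+fo)).

    For conv kernels (Cout, Cin, *k), fan_in = Cin * prod(k) and
    fan_out = Cout * prod(k) unless given explicitly.
    """
    if fan_in is None or fan_out is None:
        if len(shape) < 2:
            fan_in = fan_out = shape[0]
        else:
            receptive = int(np.prod(shape[2:])) if len(shape) > 2 else 1
            fan_out = shape[0] * receptive
            fan_in = shape[1] * receptive
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)
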