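"""Reverse-mode automatic differentiation over NumPy arrays.

This is the package's compute core: a deliberately small tape-based
autodiff engine providing exactly the operations the sequence model
needs (embedding lookup, length-preserving 1-D convolution, layer
normalization, batched matrix products, softmax, and the scalar
reductions used by the loss).  All arithmetic is float64.

A :class:`Tensor` wraps an ``ndarray`` and remembers how it was
produced; calling :meth:`Tensor.backward` on a scalar result
accumulates gradients into every reachable leaf created with
``requires_grad=True``.  Gradients flowing through broadcast
operations are summed back down to the leaf's shape.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "matmul",
    "relu",
    "log",
    "clip",
    "power",
    "softmax",
    "conv1d",
    "layer_norm",
    "embedding",
    "take_position",
    "pick",
    "reduce_mean",
    "reduce_sum",
    "reshape",
    "transpose",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray node in the differentiation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- convenience -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def item(self) -> float:
        return float(self.data)

    # -- backprop ----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (a scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise & linear algebra
# ---------------------------------------------------------------------------

def add(a: Tensor, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a: Tensor, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with broadcasting over leading axes."""
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a.accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b.accumulate(_unbroadcast(gb, b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(g * mask)

    return Tensor(out_data, parents=(x,), backward=backward)


def log(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out_data = np.log(x.data)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(g / x.data)

    return Tensor(out_data, parents=(x,), backward=backward)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient is passed only where values were in range."""
    x = _as_tensor(x)
    out_data = np.clip(x.data, lo, hi)
    inside = (x.data >= lo) & (x.data <= hi)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(g * inside)

    return Tensor(out_data, parents=(x,), backward=backward)


def power(x: Tensor, exponent: float) -> Tensor:
    """Elementwise ``x ** exponent`` for a constant real exponent ≥ 0."""
    x = _as_tensor(x)
    out_data = x.data ** exponent

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            if exponent == 0:
                x.accumulate(np.zeros_like(x.data))
            else:
                x.accumulate(g * exponent * x.data ** (exponent - 1))

    return Tensor(out_data, parents=(x,), backward=backward)


def softmax(x: Tensor) -> Tensor:
    """Numerically stable softmax over the last axis."""
    x = _as_tensor(x)
    shifted = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=-1, keepdims=True)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            dot = (g * out_data).sum(axis=-1, keepdims=True)
            x.accumulate((g - dot) * out_data)

    return Tensor(out_data, parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# sequence ops
# ---------------------------------------------------------------------------

def conv1d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Length-preserving 1-D convolution along the sequence axis.

    ``x`` has shape (batch, L, C_in); ``weight`` has shape
    (K, C_in, C_out) with K odd; symmetric zero padding of K//2 keeps
    the output length at L.
    """
    x, weight, bias = _as_tensor(x), _as_tensor(weight), _as_tensor(bias)
    batch, length, c_in = x.data.shape
    k, wc_in, c_out = weight.data.shape
    if wc_in != c_in:
        raise ValueError(f"channel mismatch: input {c_in}, weight {wc_in}")
    if k % 2 != 1:
        raise ValueError("kernel width must be odd for symmetric padding")
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (pad, pad), (0, 0)))
    # windows[b, l, k, c] == xp[b, l + k, c]
    windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
    windows = np.moveaxis(windows, -1, 2)  # (batch, L, K, C_in)
    win_flat = windows.reshape(batch, length, k * c_in)
    w_flat = weight.data.reshape(k * c_in, c_out)
    out_data = win_flat @ w_flat + bias.data

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            g_win = (g @ w_flat.T).reshape(batch, length, k, c_in)
            gxp = np.zeros_like(xp)
            for kk in range(k):
                gxp[:, kk:kk + length, :] += g_win[:, :, kk, :]
            x.accumulate(gxp[:, pad:pad + length, :])
        if weight.requires_grad:
            gw = np.einsum("blf,blo->fo", win_flat, g)
            weight.accumulate(gw.reshape(k, c_in, c_out))
        if bias.requires_grad:
            bias.accumulate(g.sum(axis=(0, 1)))

    return Tensor(out_data, parents=(x, weight, bias), backward=backward)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the channel (last) axis, then scale and shift."""
    x, gain, bias = _as_tensor(x), _as_tensor(gain), _as_tensor(bias)
    mu = x.data.mean(axis=-1, keepdims=True)
    centered = x.data - mu
    var = (centered ** 2).mean(axis=-1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = centered * inv_std
    out_data = gain.data * xhat + bias.data
    n = x.data.shape[-1]

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            g_xhat = g * gain.data
            g_var = (g_xhat * centered).sum(axis=-1, keepdims=True) * (-0.5) * inv_std ** 3
            g_mu = -(g_xhat * inv_std).sum(axis=-1, keepdims=True) + \
                g_var * (-2.0 / n) * centered.sum(axis=-1, keepdims=True)
            gx = g_xhat * inv_std + g_var * 2.0 * centered / n + g_mu / n
            x.accumulate(gx)
        if gain.requires_grad:
            gg = g * xhat
            gain.accumulate(_unbroadcast(gg, gain.shape))
        if bias.requires_grad:
            bias.accumulate(_unbroadcast(g, bias.shape))

    return Tensor(out_data, parents=(x, gain, bias), backward=backward)


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``weight[ids]`` with scatter-add backward."""
    weight = _as_tensor(weight)
    ids = np.asarray(ids)
    out_data = weight.data[ids]

    def backward(g: np.ndarray) -> None:
        if weight.requires_grad:
            gw = np.zeros_like(weight.data)
            np.add.at(gw, ids, g)
            weight.accumulate(gw)

    return Tensor(out_data, parents=(weight,), backward=backward)


def take_position(x: Tensor, position: int) -> Tensor:
    """Select one sequence position: (batch, L, C) -> (batch, C)."""
    x = _as_tensor(x)
    out_data = x.data[:, position, :]

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[:, position, :] = g
            x.accumulate(gx)

    return Tensor(out_data, parents=(x,), backward=backward)


def pick(x: Tensor, index: np.ndarray) -> Tensor:
    """Gather one entry per row along the last axis: (N, C), (N,) -> (N,)."""
    x = _as_tensor(x)
    index = np.asarray(index)
    rows = np.arange(x.data.shape[0])
    out_data = x.data[rows, index]

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[rows, index] = g
            x.accumulate(gx)

    return Tensor(out_data, parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# reductions and reshapes
# ---------------------------------------------------------------------------

def reduce_sum(x: Tensor, axis: int | None = None) -> Tensor:
    x = _as_tensor(x)
    out_data = x.data.sum(axis=axis)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            if axis is None:
                x.accumulate(np.broadcast_to(g, x.shape).copy())
            else:
                x.accumulate(np.broadcast_to(np.expand_dims(g, axis), x.shape).copy())

    return Tensor(out_data, parents=(x,), backward=backward)


def reduce_mean(x: Tensor, axis: int | None = None) -> Tensor:
    x = _as_tensor(x)
    count = x.data.size if axis is None else x.data.shape[axis]
    return mul(reduce_sum(x, axis=axis), 1.0 / count)


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    x = _as_tensor(x)
    out_data = x.data.reshape(shape)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(g.reshape(x.shape))

    return Tensor(out_data, parents=(x,), backward=backward)


def transpose(x: Tensor, axes: tuple[int, ...]) -> Tensor:
    x = _as_tensor(x)
    out_data = x.data.transpose(axes)
    inverse = tuple(np.argsort(axes))

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(g.transpose(inverse))

    return Tensor(out_data, parents=(x,), backward=backward)
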