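"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the spike-to-image decoder needs:
broadcasting arithmetic, matrix multiply, axis reductions, reshape,
LeakyReLU / sigmoid, sqrt/power, and strided 2D convolution and transposed
convolution (via unfold/fold).  Gradients flow through a dynamically built
tape; call :meth:`Tensor.backward` on a scalar loss.

Convolutions follow the usual deep-learning conventions: activations are
``(N, C, H, W)``, convolution weights ``(out_ch, in_ch, k, k)``, transposed
convolution weights ``(in_ch, out_ch, k, k)``.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = ["Tensor", "conv2d", "conv_transpose2d", "no_grad"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to the original operand shape."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- plumbing -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=g.dtype)
        self.grad += g

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _node(self, data, prev, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad or p._prev for p in prev):
            out.requires_grad = any(p.requires_grad for p in prev)
            out._prev = prev
            out._backward = backward
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free the tape as we go
            node._backward = None
            node._prev = ()

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        return self._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return self._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return self._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
            )

        return self._node(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return self._node(self.data**exponent, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accumulate(g / (2.0 * np.maximum(out_data, 1e-30)))

        return self._node(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            if _wants_grad(self):
                self._accumulate(g @ other.data.T)
            if _wants_grad(other):
                other._accumulate(self.data.T @ g)

        return self._node(self.data @ other.data, (self, other), backward)

    # -- reductions & shape -------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return self._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g):
            self._accumulate(g.reshape(self.data.shape))

        return self._node(self.data.reshape(shape), (self,), backward)

    # -- nonlinearities ------------------------------------------------------

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * np.where(mask, 1.0, slope))

        return self._node(
            np.where(mask, self.data, slope * self.data), (self,), backward
        )

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return self._node(out_data, (self,), backward)


def _wants_grad(t: Tensor) -> bool:
    return t.requires_grad or bool(t._prev)


# -- convolution helpers -----------------------------------------------------


def _unfold(x: np.ndarray, k: int, stride: int, padding: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    n, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    hp, wp = x.shape[2], x.shape[3]
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, ho, wo, k, k),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3),
        writeable=False,
    )
    # (N, C, k, k, Ho, Wo) -> (N, C*k*k, L)
    return np.ascontiguousarray(windows.transpose(0, 1, 4, 5, 2, 3)).reshape(
        n, c * k * k, ho * wo
    )


def _fold(
    cols: np.ndarray,
    out_spatial: tuple[int, int],
    n_ch: int,
    k: int,
    stride: int,
    padding: int,
    patch_grid: tuple[int, int],
) -> np.ndarray:
    """Scatter-add inverse of :func:`_unfold`.

    ``cols`` is (N, n_ch*k*k, Ho*Wo) with patch grid (Ho, Wo); returns the
    (N, n_ch, H, W) array whose unfold would have produced those patches.
    """
    n = cols.shape[0]
    ho, wo = patch_grid
    h, w = out_spatial
    out = np.zeros((n, n_ch, h + 2 * padding, w + 2 * padding), dtype=cols.dtype)
    patches = cols.reshape(n, n_ch, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                patches[:, :, i, j]
            )
    if padding:
        out = out[:, :, padding:-padding, padding:-padding]
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int, padding: int) -> Tensor:
    """Strided 2D cross-correlation with bias."""
    n, c, h, w = x.data.shape
    o, ci, k, _ = weight.data.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {ci}")
    ho = (h + 2 * padding - k) // stride + 1
    wo = (w + 2 * padding - k) // stride + 1
    cols = _unfold(x.data, k, stride, padding)
    wmat = weight.data.reshape(o, -1)
    out_data = (wmat[None] @ cols).reshape(n, o, ho, wo) + bias.data[None, :, None, None]

    def backward(g):
        gmat = g.reshape(n, o, ho * wo)
        if weight.requires_grad:
            weight._accumulate(
                np.einsum("nol,nkl->ok", gmat, cols).reshape(weight.data.shape)
            )
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if _wants_grad(x):
            dcols = wmat.T[None] @ gmat
            x._accumulate(_fold(dcols, (h, w), c, k, stride, padding, (ho, wo)))

    return x._node(out_data, (x, weight, bias), backward)


def conv_transpose2d(
    x: Tensor, weight: Tensor, bias: Tensor, stride: int, padding: int
) -> Tensor:
    """Strided 2D transposed convolution (the adjoint of conv2d)."""
    n, c, h, w = x.data.shape
    ci, o, k, _ = weight.data.shape
    if ci != c:
        raise ValueError(f"conv_transpose2d channel mismatch: input {c}, weight {ci}")
    hout = (h - 1) * stride - 2 * padding + k
    wout = (w - 1) * stride - 2 * padding + k
    xflat = x.data.reshape(n, c, h * w)
    wmat = weight.data.reshape(c, o * k * k)
    cols = np.einsum("ck,ncl->nkl", wmat, xflat)
    out_data = _fold(cols, (hout, wout), o, k, stride, padding, (h, w))
    out_data = out_data + bias.data[None, :, None, None]

    def backward(g):
        gcols = _unfold(g, k, stride, padding)  # (N, O*k*k, H*W)
        if weight.requires_grad:
            weight._accumulate(
                np.einsum("ncl,nkl->ck", xflat, gcols).reshape(weight.data.shape)
            )
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if _wants_grad(x):
            dx = np.einsum("ck,nkl->ncl", wmat, gcols).reshape(n, c, h, w)
            x._accumulate(dx)

    return x._node(out_data, (x, weight, bias), backward)
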