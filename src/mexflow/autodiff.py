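"""A small reverse-mode automatic-differentiation engine over numpy arrays.

The network in this package is deliberately tiny (tens of thousands of
parameters, 28x28 inputs), so it runs on a compact tape-based autodiff core
instead of a heavyweight deep-learning framework: every operation records
its parents and a closure that accumulates gradients, and ``backward`` walks
the tape in reverse topological order. Convolutions use im2col + matmul,
which keeps the inner loops inside BLAS.

Only the operations the flow network needs are implemented; all arithmetic
is float32 by default for speed, gradients share the dtype of the data.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence, Tuple

import numpy as np

__all__ = ["Tensor", "concat", "stack_backwardable"]

_PATH_CACHE: dict = {}


def _einsum(subscripts: str, *operands: np.ndarray) -> np.ndarray:
    """np.einsum with the contraction path cached per operand-shape set."""
    key = (subscripts, tuple(op.shape for op in operands))
    path = _PATH_CACHE.get(key)
    if path is None:
        path = np.einsum_path(subscripts, *operands, optimize="optimal")[0]
        _PATH_CACHE[key] = path
    return np.einsum(subscripts, *operands, optimize=path)


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Tuple["Tensor", ...] = (),
                 backward: Optional[Callable[[np.ndarray], None]] = None):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    # -- basics ------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Accumulate gradients of this (scalar unless ``grad`` given) output."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list = []
        seen = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    @staticmethod
    def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
        """Sum a gradient down to ``shape`` after numpy broadcasting."""
        while g.ndim > len(shape):
            g = g.sum(axis=0)
        for ax, s in enumerate(shape):
            if s == 1 and g.shape[ax] != 1:
                g = g.sum(axis=ax, keepdims=True)
        return g

    # -- elementwise arithmetic --------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accum(self._unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(self._unbroadcast(g, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bw(g):
            self._accum(-g)
        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accum(self._unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(self._unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accum(self._unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(self._unbroadcast(
                    -g * self.data / (other.data ** 2), other.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    def pow_const(self, p: float) -> "Tensor":
        out_data = self.data ** p

        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor(out_data, parents=(self,), backward=bw)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bw)

    def log(self) -> "Tensor":
        def bw(g):
            self._accum(g / self.data)
        return Tensor(np.log(self.data), parents=(self,), backward=bw)

    def relu(self) -> "Tensor":
        mask = self.data > 0
        def bw(g):
            self._accum(g * mask)
        return Tensor(self.data * mask, parents=(self,), backward=bw)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(self,), backward=bw)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        orig = self.shape
        def bw(g):
            self._accum(g.reshape(orig))
        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bw)

    def transpose(self, axes) -> "Tensor":
        inv = np.argsort(axes)
        def bw(g):
            self._accum(g.transpose(inv))
        return Tensor(self.data.transpose(axes), parents=(self,), backward=bw)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, shape))

        return Tensor(out_data, parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == out_data
        # ties split evenly so the gradient stays well-defined
        counts = mask.sum(axis=axis, keepdims=True)

        def bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.where(mask, g / counts, 0.0))

        return Tensor(out_data if keepdims else out_data.squeeze(axis),
                      parents=(self,), backward=bw)

    def logsumexp(self, axis: int = 1) -> "Tensor":
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        s = e.sum(axis=axis, keepdims=True)
        out_data = (m + np.log(s)).squeeze(axis)
        softmax = e / s

        def bw(g):
            self._accum(np.expand_dims(g, axis) * softmax)

        return Tensor(out_data, parents=(self,), backward=bw)

    def gather(self, index: np.ndarray, axis: int = 1) -> "Tensor":
        """Pick one entry per row: out[i] = self[i, index[i]] (2-D only)."""
        assert self.ndim == 2 and axis == 1
        index = np.asarray(index, dtype=np.int64)
        rows = np.arange(self.shape[0])
        out_data = self.data[rows, index]

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, (rows, index), g)
            self._accum(full)

        return Tensor(out_data, parents=(self,), backward=bw)

    # -- linear algebra ------------------------------------------------------
    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out_data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor(out_data, parents=(self, other), backward=bw)

    __matmul__ = matmul

    # -- image ops -----------------------------------------------------------
    def pad2d(self, pad: int) -> "Tensor":
        """Zero-pad the last two axes of a (B, C, H, W) tensor."""
        if pad == 0:
            return self
        p = ((0, 0), (0, 0), (pad, pad), (pad, pad))
        out_data = np.pad(self.data, p)

        def bw(g):
            self._accum(g[:, :, pad:-pad, pad:-pad])

        return Tensor(out_data, parents=(self,), backward=bw)

    def pad2d_edge(self, pad: int) -> "Tensor":
        """Replicate-pad the last two axes of a (B, C, H, W) tensor.

        Unlike zero padding this introduces no artificial dark frame around
        inputs whose background level is non-zero.
        """
        if pad == 0:
            return self
        p = ((0, 0), (0, 0), (pad, pad), (pad, pad))
        out_data = np.pad(self.data, p, mode="edge")

        def bw(g):
            # fold the replicated margins back onto the border pixels
            core = np.array(g[:, :, pad:-pad, pad:-pad], copy=True)
            core[:, :, 0, :] += g[:, :, :pad, pad:-pad].sum(axis=2)
            core[:, :, -1, :] += g[:, :, -pad:, pad:-pad].sum(axis=2)
            core[:, :, :, 0] += g[:, :, pad:-pad, :pad].sum(axis=3)
            core[:, :, :, -1] += g[:, :, pad:-pad, -pad:].sum(axis=3)
            core[:, :, 0, 0] += g[:, :, :pad, :pad].sum(axis=(2, 3))
            core[:, :, 0, -1] += g[:, :, :pad, -pad:].sum(axis=(2, 3))
            core[:, :, -1, 0] += g[:, :, -pad:, :pad].sum(axis=(2, 3))
            core[:, :, -1, -1] += g[:, :, -pad:, -pad:].sum(axis=(2, 3))
            self._accum(core)

        return Tensor(out_data, parents=(self,), backward=bw)

    def conv2d(self, weight: "Tensor", bias: Optional["Tensor"] = None,
               padding: int = 0, pad_mode: str = "zero",
               relu: bool = False) -> "Tensor":
        """'Same'-capable 2-D convolution (cross-correlation), stride 1.

        ``self``: (B, C, H, W); ``weight``: (O, C, kh, kw); ``bias``: (O,).
        1x1 kernels reduce to a channel matmul; larger kernels go through a
        sliding-window einsum, with the input gradient computed as a full
        correlation with the spatially flipped, channel-transposed weights.
        """
        O, _, kh, kw = weight.shape
        if kh == 1 and kw == 1:
            return self._conv1x1(weight, bias, relu)
        if padding:
            x = (self.pad2d_edge(padding) if pad_mode == "edge"
                 else self.pad2d(padding))
        else:
            x = self
        B, C, H, W = x.shape
        oh, ow = H - kh + 1, W - kw + 1
        cols_view = np.lib.stride_tricks.sliding_window_view(
            x.data, (kh, kw), axis=(2, 3))          # (B, C, oh, ow, kh, kw)
        out_data = _einsum("bchwij,ocij->bohw", cols_view, weight.data)
        if bias is not None:
            out_data += bias.data[None, :, None, None]
        mask = (out_data > 0) if relu else None
        if relu:
            out_data *= mask
        parents = (x, weight) + ((bias,) if bias is not None else ())

        def bw(g):
            if relu:
                g = g * mask
            if weight.requires_grad:
                weight._accum(_einsum("bohw,bchwij->ocij", g, cols_view))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gp = np.pad(np.ascontiguousarray(g),
                            ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
                gcols = np.lib.stride_tricks.sliding_window_view(
                    gp, (kh, kw), axis=(2, 3))       # (B, O, H, W, kh, kw)
                wflip = np.ascontiguousarray(weight.data[:, :, ::-1, ::-1])
                x._accum(_einsum("bohwij,ocij->bchw", gcols, wflip))

        return Tensor(out_data, parents=parents, backward=bw)

    def _conv1x1(self, weight: "Tensor", bias: Optional["Tensor"],
                 relu: bool = False) -> "Tensor":
        B, C, H, W = self.shape
        O = weight.shape[0]
        wmat = weight.data.reshape(O, C)
        out_data = _einsum("oc,bchw->bohw", wmat, self.data)
        if bias is not None:
            out_data += bias.data[None, :, None, None]
        mask = (out_data > 0) if relu else None
        if relu:
            out_data *= mask
        parents = (self, weight) + ((bias,) if bias is not None else ())

        def bw(g):
            if relu:
                g = g * mask
            if weight.requires_grad:
                weight._accum(_einsum("bohw,bchw->oc", g, self.data).reshape(weight.shape))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                self._accum(_einsum("oc,bohw->bchw", wmat, g))

        return Tensor(out_data, parents=parents, backward=bw)

    def maxpool2d(self, k: int = 2, stride: Optional[int] = None,
                  padding: int = 0) -> "Tensor":
        """Max pooling over (B, C, H, W); default non-overlapping k x k."""
        stride = stride or k
        x = self.pad2d(padding) if padding else self
        B, C, H, W = x.shape
        oh = (H - k) // stride + 1
        ow = (W - k) // stride + 1
        win = np.lib.stride_tricks.sliding_window_view(
            x.data, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
        flat = win.reshape(B, C, oh, ow, k * k)
        arg = flat.argmax(axis=-1)
        out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

        def bw(g):
            gx = np.zeros((B, C, H, W), dtype=x.data.dtype)
            if stride == k:
                # non-overlapping windows: scatter without collisions
                gwin = np.zeros((B, C, oh, ow, k * k), dtype=gx.dtype)
                np.put_along_axis(gwin, arg[..., None],
                                  np.ascontiguousarray(g)[..., None], axis=-1)
                gx[:, :, :oh * k, :ow * k] = gwin.reshape(
                    B, C, oh, ow, k, k).transpose(0, 1, 2, 4, 3, 5).reshape(
                    B, C, oh * k, ow * k)
            else:
                # overlapping windows: one vectorised add per kernel offset
                for off in range(k * k):
                    mask = arg == off
                    if not mask.any():
                        continue
                    i, j = divmod(off, k)
                    contrib = np.where(mask, g, 0.0)
                    gx[:, :, i:i + (oh - 1) * stride + 1:stride,
                       j:j + (ow - 1) * stride + 1:stride] += contrib
            x._accum(gx)

        return Tensor(np.ascontiguousarray(out_data), parents=(x,), backward=bw)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=bw)


def stack_backwardable(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Stack tensors along a new axis with gradient routing."""
    tensors = list(tensors)
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor(out_data, parents=tuple(tensors), backward=bw)
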