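"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` runs the chain rule over the recorded graph in
reverse topological order.  Only the operations needed by the CAM pipeline
are provided: broadcast arithmetic, matmul, elementwise nonlinearities,
reductions, reshaping/concatenation, 2-D convolution (with groups), max
pooling, bilinear resampling and image-plane rotation.

All data is kept in ``float64`` by default for numerically honest gradient
checks; layers may down-cast if memory ever matters (it does not at the
problem sizes this package targets).
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concatenate", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    return np.asarray(x, dtype=np.float64)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node._accumulate(g)
                continue
            node._accumulate_or_route(g, grads)

    def _accumulate_or_route(self, g: np.ndarray, grads: dict[int, np.ndarray]) -> None:
        # leaves accumulate into .grad; interior nodes route to parents
        if not self._parents:
            self._accumulate(g)
            return
        parts = self._backward(g)
        for p, pg in zip(self._parents, parts):
            if pg is None or not p.requires_grad:
                continue
            key = id(p)
            if key in grads:
                grads[key] = grads[key] + pg
            else:
                grads[key] = pg
        if self.grad is not None or self._retains():
            self._accumulate(g)

    def _retains(self) -> bool:
        return False

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- conveniences ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float64))

    def __add__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def bw(g):
            return (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def bw(g):
            return (_unbroadcast(g * b.data, a.data.shape),
                    _unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def bw(g):
            return (_unbroadcast(g / b.data, a.data.shape),
                    _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, p: float):
        a = self
        pd = float(p)

        def bw(g):
            return (g * pd * a.data ** (pd - 1.0),)

        return Tensor._make(a.data ** pd, (a,), bw)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def bw(g):
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            return (_unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), bw)

    # -- elementwise -------------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._make(out_data, (a,), lambda g: (g * out_data,))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: (g / a.data,))

    def sqrt(self):
        return self ** 0.5

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: (g * mask,))

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._make(out_data, (a,), lambda g: (g * out_data * (1.0 - out_data),))

    def silu(self):
        return self * self.sigmoid()

    def abs(self):
        a = self
        sign = np.sign(a.data)
        return Tensor._make(np.abs(a.data), (a,), lambda g: (g * sign,))

    def clip(self, lo: float, hi: float):
        a = self
        mask = (a.data > lo) & (a.data < hi)
        return Tensor._make(np.clip(a.data, lo, hi), (a,), lambda g: (g * mask,))

    # -- reductions / shaping ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bw(g):
            if axis is None:
                return (np.broadcast_to(g, a.data.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, a.data.shape).copy(),)

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape
        return Tensor._make(a.data.reshape(shape), (a,), lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)
        return Tensor._make(a.data.transpose(axes), (a,),
                            lambda g: (g.transpose(inv),))

    def __getitem__(self, idx):
        a = self

        def bw(g):
            gx = np.zeros_like(a.data)
            np.add.at(gx, idx, g)
            return (gx,)

        return Tensor._make(a.data[idx], (a,), bw)


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(np.concatenate([t.data for t in ts], axis=axis), ts, bw)


# ---------------------------------------------------------------------------
# spatial operations (NCHW layout)
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW, square stride/padding, grouped."""
    n, cin, h, wd = x.data.shape
    cout, cpg, kh, kw = w.data.shape
    if cin != cpg * groups:
        raise ValueError(f"channel mismatch: input {cin}, weight expects {cpg * groups}")
    s, p = int(stride), int(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    ho, wo = win.shape[2], win.shape[3]
    win_g = win.reshape(n, groups, cpg, ho, wo, kh, kw)
    w_g = w.data.reshape(groups, cout // groups, cpg, kh, kw)
    out = np.einsum("ngchwij,gocij->ngohw", win_g, w_g, optimize=True)
    out = out.reshape(n, cout, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, cout, 1, 1)

    def bw(g):
        g_g = g.reshape(n, groups, cout // groups, ho, wo)
        gw = np.einsum("ngchwij,ngohw->gocij", win_g, g_g, optimize=True)
        gw = gw.reshape(cout, cpg, kh, kw)
        gwin = np.einsum("gocij,ngohw->ngchwij", w_g, g_g, optimize=True)
        gwin = gwin.reshape(n, cin, ho, wo, kh, kw)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i:i + s * (ho - 1) + 1:s,
                    j:j + s * (wo - 1) + 1:s] += gwin[:, :, :, :, i, j]
        gx = gxp[:, :, p:p + h, p:p + wd] if p else gxp
        gb = g.sum(axis=(0, 2, 3)) if b is not None else None
        return (gx, gw, gb)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, bw)


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    n, c, h, w = x.data.shape
    k, s, p = int(kernel), int(stride), int(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)),
                constant_values=-np.inf) if p else x.data
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    ho, wo = win.shape[2], win.shape[3]
    flat = win.reshape(n, c, ho, wo, k * k)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    ki, kj = np.divmod(arg, k)
    ni, ci, oi, oj = np.meshgrid(np.arange(n), np.arange(c), np.arange(ho),
                                 np.arange(wo), indexing="ij")
    rows = oi * s + ki
    cols = oj * s + kj

    def bw(g):
        gxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        np.add.at(gxp, (ni, ci, rows, cols), g)
        return (gxp[:, :, p:p + h, p:p + w] if p else gxp,)

    return Tensor._make(out, (x,), bw)


def _bilinear_coords(ys: np.ndarray, xs: np.ndarray, h: int, w: int,
                     mode: str = "zeros"):
    """Corner indices + weights for bilinear sampling at real coords (ys, xs).

    ``mode='zeros'``: out-of-range corners get zero weight (rotation fill);
    ``mode='edge'``: corner indices are clamped to the frame, replicating the
    border (the convention for plain resizing, so constants stay constant).
    """
    valid = (ys >= -0.5) & (ys <= h - 0.5) & (xs >= -0.5) & (xs <= w - 0.5)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    dy = ys - y0
    dx = xs - x0
    corners = []
    for oy, ox in ((0, 0), (0, 1), (1, 0), (1, 1)):
        yy = y0 + oy
        xx = x0 + ox
        wgt = (dy if oy else 1 - dy) * (dx if ox else 1 - dx)
        if mode == "zeros":
            inb = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w) & valid
            wgt = wgt * inb
        corners.append((np.clip(yy, 0, h - 1), np.clip(xx, 0, w - 1), wgt))
    return corners, valid


def _bilinear_sample(x: Tensor, ys: np.ndarray, xs: np.ndarray,
                     mode: str = "zeros") -> Tensor:
    """Sample x (N,C,H,W) at output grid of source coords ys/xs (Ho,Wo)."""
    n, c, h, w = x.data.shape
    corners, _ = _bilinear_coords(ys, xs, h, w, mode)
    out = np.zeros((n, c) + ys.shape)
    for yy, xx, wgt in corners:
        out += x.data[:, :, yy, xx] * wgt

    nc_idx = np.arange(n * c)[:, None, None]

    def bw(g):
        gx = np.zeros_like(x.data)
        gview = gx.reshape(n * c, h, w)
        for yy, xx, wgt in corners:
            # scatter-add; corner indices are shared across samples/channels
            np.add.at(gview, (nc_idx, yy[None], xx[None]),
                      (g * wgt).reshape(n * c, *ys.shape))
        return (gx,)

    return Tensor._make(out, (x,), bw)


def resize_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize (half-pixel centers, no corner alignment)."""
    n, c, h, w = x.data.shape
    ys = (np.arange(out_h) + 0.5) * (h / out_h) - 0.5
    xs = (np.arange(out_w) + 0.5) * (w / out_w) - 0.5
    ys, xs = np.meshgrid(ys, xs, indexing="ij")
    return _bilinear_sample(x, ys, xs, mode="edge")


def rotate(x: Tensor, angle_deg: float) -> Tensor:
    """Rotate about the image centre, bilinear, zero fill (NCHW)."""
    n, c, h, w = x.data.shape
    ys, xs = _rotation_grid(h, w, angle_deg)
    return _bilinear_sample(x, ys, xs)


def _rotation_grid(h: int, w: int, angle_deg: float):
    """Source coordinates for an ``angle_deg`` rotation (inverse mapping)."""
    t = np.deg2rad(angle_deg)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                         indexing="ij")
    yr = yy - cy
    xr = xx - cx
    ys = np.cos(t) * yr + np.sin(t) * xr + cy
    xs = -np.sin(t) * yr + np.cos(t) * xr + cx
    return ys, xs


def rotation_valid_mask(h: int, w: int, angle_deg: float) -> np.ndarray:
    """Boolean (h, w) mask of pixels whose rotated source lies inside the frame."""
    ys, xs = _rotation_grid(h, w, angle_deg)
    return (ys >= 0) & (ys <= h - 1) & (xs >= 0) & (xs <= w - 1)
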