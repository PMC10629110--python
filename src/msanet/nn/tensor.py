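"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it so that :meth:`Tensor.backward` can accumulate gradients through the
graph.  The op set is deliberately small — elementwise arithmetic, matmul,
reductions, shape manipulation, 2-D (grouped / strided / transposed)
convolution and the activations the network needs — but each op is fully
batched and vectorised, so a complete encoder–decoder forward/backward pass
runs at BLAS speed.

Convolutions use an im2col/col2im strategy: the forward pass gathers sliding
windows into one contiguous matrix product, and the input-gradient scatters
back with one vectorised accumulation per kernel offset (O(k^2) slice adds,
no per-pixel Python work).
"""

from __future__ import annotations

import numpy as np

from . import _dwconv as _dw

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "avg_pool2d",
    "relu",
    "clip",
    "sigmoid",
    "exp",
    "log",
    "softmax",
    "log_softmax",
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
    """An ndarray node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

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
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff driver --------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free graph buffers as soon as they are consumed
                node._backward = None
                node._parents = ()

    def _accum(self, grad: np.ndarray):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def zero_grad(self):
        self.grad = None

    # -- elementwise arithmetic ------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        if isinstance(other, (int, float)):
            # python scalars stay scalars: no dtype promotion, no extra node
            def backward(g):
                self._accum(g)

            return Tensor._make(self.data + other, (self,), backward)
        other = Tensor._coerce(other)

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return (-self) + other if isinstance(other, (int, float)) \
            else Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            def backward(g):
                self._accum(g * other)

            return Tensor._make(self.data * other, (self,), backward)
        other = Tensor._coerce(other)

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._coerce(other) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g):
            self._accum(g * e * self.data ** (e - 1.0))

        return Tensor._make(self.data ** e, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        a, b = self.data, other.data

        def backward(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        return Tensor._make(a @ b, (self, other), backward)

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape manipulation ----------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accum(np.ascontiguousarray(g.transpose(inv)))

        return Tensor._make(np.ascontiguousarray(self.data.transpose(axes)), (self,), backward)


# -- n-ary / functional ops ------------------------------------------------


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accum(g[tuple(idx)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def relu(x: Tensor) -> Tensor:
    x = Tensor._coerce(x)
    mask = x.data > 0

    def backward(g):
        x._accum(g * mask)

    return Tensor._make(np.where(mask, x.data, 0.0), (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    x = Tensor._coerce(x)
    d = x.data
    out = np.empty_like(d)
    pos = d >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
    ez = np.exp(d[~pos])  # stable branch for large negative inputs
    out[~pos] = ez / (1.0 + ez)

    def backward(g):
        x._accum(g * out * (1.0 - out))

    return Tensor._make(out, (x,), backward)


def exp(x: Tensor) -> Tensor:
    x = Tensor._coerce(x)
    out = np.exp(x.data)

    def backward(g):
        x._accum(g * out)

    return Tensor._make(out, (x,), backward)


def log(x: Tensor) -> Tensor:
    x = Tensor._coerce(x)

    def backward(g):
        x._accum(g / x.data)

    return Tensor._make(np.log(x.data), (x,), backward)


def clip(x: Tensor, lo: float | None = None, hi: float | None = None) -> Tensor:
    """Clamp values; gradient is passed through inside the active range."""
    x = Tensor._coerce(x)
    out = np.clip(x.data, lo, hi)
    inside = np.ones_like(x.data, dtype=bool)
    if lo is not None:
        inside &= x.data >= lo
    if hi is not None:
        inside &= x.data <= hi

    def backward(g):
        x._accum(g * inside)

    return Tensor._make(out, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - log(exp(shifted).sum(axis=axis, keepdims=True))


# -- 2-D convolution -------------------------------------------------------


def _pad_hw(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))


def _windows(x, kh, kw, stride, ph, pw):
    xp = _pad_hw(x, ph, pw)
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return win[:, :, ::stride, ::stride]  # (n, cin, ho, wo, kh, kw) view


def _conv_forward(x, w, stride, ph, pw, groups):
    """Correlate NCHW input with (Cout, Cin/g, kh, kw) weights.

    Returns (out, cache); the cache carries the im2col matrix (dense
    groups) or the window view (depth-wise) for reuse in the weight
    gradient.
    """
    n, cin, _, _ = x.shape
    cout, cing, kh, kw = w.shape
    win = _windows(x, kh, kw, stride, ph, pw)
    ho, wo = win.shape[2], win.shape[3]
    if groups == 1:
        col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, cin * kh * kw
        )
        out = col @ w.reshape(cout, -1).T
        out = np.ascontiguousarray(out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2))
        return out, col
    if groups == cin and cing == 1 and cout == cin:
        # depth-wise: fused per-pixel tap loop (numba) or tap-wise
        # shift-and-accumulate (numpy fallback); no channel mixing
        xp = _pad_hw(x, ph, pw)
        wk = np.ascontiguousarray(w[:, 0])
        if _dw.HAVE_NUMBA:
            return _dw.dw_forward(xp, wk, stride, ho, wo), xp
        out = np.zeros((n, cin, ho, wo), dtype=x.dtype)
        for ki in range(kh):
            for kj in range(kw):
                out += wk[None, :, ki, kj, None, None] * xp[
                    :, :, ki : ki + stride * ho : stride,
                    kj : kj + stride * wo : stride]
        return out, xp
    # general grouped conv
    cpg_in, cpg_out = cin // groups, cout // groups
    wg = w.reshape(groups, cpg_out, cpg_in, kh, kw)
    wing = win.reshape(n, groups, cpg_in, ho, wo, kh, kw)
    out = np.einsum("ngchwij,gdcij->ngdhw", wing, wg, optimize=True)
    return np.ascontiguousarray(out.reshape(n, cout, ho, wo)), win


def _conv_input_grad(g, w, x_shape, stride, ph, pw, groups):
    """Scatter output-gradient back to the (padded, then cropped) input."""
    n, cin, h, wid = x_shape
    cout, cing, kh, kw = w.shape
    hp, wp = h + 2 * ph, wid + 2 * pw
    ho, wo = g.shape[2], g.shape[3]
    if groups == 1:
        # one GEMM, then O(k^2) NHWC strided adds and a single transpose
        gcol = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, cout)
        wmat = w.transpose(0, 2, 3, 1).reshape(cout, kh * kw * cin)
        dcol = (gcol @ wmat).reshape(n, ho, wo, kh, kw, cin)
        dxp = np.zeros((n, hp, wp, cin), dtype=g.dtype)
        for ki in range(kh):
            for kj in range(kw):
                dxp[:, ki : ki + stride * ho : stride,
                    kj : kj + stride * wo : stride, :] += dcol[:, :, :, ki, kj, :]
        if ph or pw:
            dxp = dxp[:, ph : hp - ph, pw : wp - pw, :]
        return np.ascontiguousarray(dxp.transpose(0, 3, 1, 2))
    if groups == cin and cing == 1 and cout == cin:
        wk = np.ascontiguousarray(w[:, 0])  # (c, kh, kw)
        if _dw.HAVE_NUMBA:
            dxp = _dw.dw_input_grad(g, wk, stride, hp, wp)
            return dxp[:, :, ph : hp - ph, pw : wp - pw] if (ph or pw) else dxp
        dxp = np.zeros((n, cin, hp, wp), dtype=g.dtype)
        for ki in range(kh):
            for kj in range(kw):
                dxp[:, :, ki : ki + stride * ho : stride,
                    kj : kj + stride * wo : stride] += g * wk[None, :, ki, kj, None, None]
    else:
        dxp = np.zeros((n, cin, hp, wp), dtype=g.dtype)
        cpg_in, cpg_out = cin // groups, cout // groups
        wg = w.reshape(groups, cpg_out, cpg_in, kh, kw)
        gg = g.reshape(n, groups, cpg_out, ho, wo)
        for ki in range(kh):
            for kj in range(kw):
                contrib = np.einsum("ngdhw,gdc->ngchw", gg, wg[:, :, :, ki, kj], optimize=True)
                dxp[:, :, ki : ki + stride * ho : stride,
                    kj : kj + stride * wo : stride] += contrib.reshape(n, cin, ho, wo)
    return dxp[:, :, ph : hp - ph, pw : wp - pw] if (ph or pw) else dxp


def _conv_weight_grad(cache, g, w_shape, groups, stride=1):
    """cache = im2col matrix (groups == 1), padded input (depth-wise) or
    window view (general grouped)."""
    cout, cing, kh, kw = w_shape
    n, ho, wo = g.shape[0], g.shape[2], g.shape[3]
    if groups == 1:
        gcol = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, cout)
        return (gcol.T @ cache).reshape(w_shape)
    cin = cache.shape[1]
    if groups == cin and cing == 1 and cout == cin:
        xp = cache
        if _dw.HAVE_NUMBA:
            return _dw.dw_weight_grad(xp, g, stride, kh, kw)[:, None]
        dw = np.empty((cin, 1, kh, kw), dtype=g.dtype)
        for ki in range(kh):
            for kj in range(kw):
                sl = xp[:, :, ki : ki + stride * ho : stride,
                        kj : kj + stride * wo : stride]
                dw[:, 0, ki, kj] = np.einsum("nchw,nchw->c", sl, g, optimize=True)
        return dw
    win = cache
    cpg_in, cpg_out = cin // groups, cout // groups
    wing = win.reshape(n, groups, cpg_in, ho, wo, kh, kw)
    gg = g.reshape(n, groups, cpg_out, ho, wo)
    dw = np.einsum("ngchwij,ngdhw->gdcij", wing, gg, optimize=True)
    return dw.reshape(w_shape)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: tuple[int, int] | int = 0, groups: int = 1) -> Tensor:
    """Grouped strided 2-D correlation of NCHW ``x`` with OIHW ``w``."""
    if isinstance(padding, int):
        padding = (padding, padding)
    ph, pw = padding
    cin = x.data.shape[1]
    if w.data.shape[1] * groups != cin:
        raise ValueError(
            f"channel mismatch: input has {cin} channels, weights expect "
            f"{w.data.shape[1] * groups} (groups={groups})"
        )
    out, cache = _conv_forward(x.data, w.data, stride, ph, pw, groups)
    x_shape = x.data.shape

    def backward(g):
        g = np.ascontiguousarray(g)
        if x.requires_grad:
            x._accum(_conv_input_grad(g, w.data, x_shape, stride, ph, pw, groups))
        if w.requires_grad:
            w._accum(_conv_weight_grad(cache, g, w.data.shape, groups, stride))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    out_t = Tensor._make(out, parents, backward)
    if b is not None:
        out_t.data += b.data[None, :, None, None]
    return out_t


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 2) -> Tensor:
    """Transposed convolution, NCHW input, weights (Cin, Cout, kh, kw).

    Output side = (in − 1) · stride + k; with k = stride this is an exact
    ×stride upsampling.  Implemented as the adjoint of :func:`conv2d`.
    """
    n, cin, h, wid = x.data.shape
    cin_w, cout, kh, kw = w.data.shape
    if cin_w != cin:
        raise ValueError(f"channel mismatch: {cin} vs weight {cin_w}")
    ho, wo = (h - 1) * stride + kh, (wid - 1) * stride + kw
    # forward = the input-gradient of a conv whose weight maps cout -> cin;
    # _conv_input_grad's (Cout_conv, Cin_conv, kh, kw) layout is exactly
    # our (cin, cout, kh, kw) array.
    w_conv = np.ascontiguousarray(w.data)
    out = _conv_input_grad(x.data, w_conv, (n, cout, ho, wo), stride, 0, 0, 1)

    def backward(g):
        g = np.ascontiguousarray(g)
        gx, col_g = _conv_forward(g, w_conv, stride, 0, 0, 1)
        if x.requires_grad:
            x._accum(gx)
        if w.requires_grad:
            dw = _conv_weight_grad(col_g, x.data, (cin, cout, kh, kw), 1)
            w._accum(dw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    out_t = Tensor._make(out, parents, backward)
    if b is not None:
        out_t.data += b.data[None, :, None, None]
    return out_t


def avg_pool2d(x: Tensor, kernel: int) -> Tensor:
    """Non-overlapping average pooling; spatial sides must divide ``kernel``."""
    n, c, h, w = x.data.shape
    if h % kernel or w % kernel:
        raise ValueError(f"spatial size {h}x{w} not divisible by pool kernel {kernel}")
    r = x.reshape(n, c, h // kernel, kernel, w // kernel, kernel)
    return r.mean(axis=5).mean(axis=3)
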