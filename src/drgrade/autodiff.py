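"""Compact reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations the two-stream bilinear classifier needs:
broadcasting arithmetic, matmul, 2-D convolution, adaptive average pooling,
channel concatenation, the nonlinearities (ReLU, sigmoid, softmax), the
signed-square-root / L2 descriptor normalisation, and an FFT-based circular
convolution used by the tensor-sketch pooling layer.

Gradients are accumulated on a tape and released by :meth:`Tensor.backward`,
which walks the graph in reverse topological order.  All data is float64;
determinism is exact because no threading or nondeterministic reduction is
involved.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "add",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "softmax",
    "log",
    "exp",
    "clip",
    "reduce_sum",
    "reduce_mean",
    "reshape",
    "transpose",
    "concat",
    "gather_rows",
    "conv2d",
    "adaptive_avg_pool2d",
    "signed_sqrt",
    "l2_normalize",
    "circular_conv_pool",
]


class Tensor:
    """A numpy array plus an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    # operator sugar
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return add(self, neg(_as_tensor(other)))

    def __rsub__(self, other):
        return add(_as_tensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __truediv__(self, other):
        other = _as_tensor(other)
        return mul(self, reciprocal(other))

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def backward(self, grad=None):
        """Backpropagate from this tensor (defaults to d self/d self = 1)."""
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)

        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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

        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def tensor(data, requires_grad=False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _make(data, parents, backward) -> Tensor:
    if any(p.requires_grad for p in parents):
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def neg(a: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(-g)

    return _make(-a.data, (a,), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def reciprocal(a: Tensor) -> Tensor:
    inv = 1.0 / a.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(-g * inv * inv)

    return _make(inv, (a,), backward)


def log(a: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    return _make(np.log(a.data), (a,), backward)


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data)

    return _make(out_data, (a,), backward)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp; gradient is passed through only inside the interval."""
    out_data = np.clip(a.data, lo, hi)
    mask = (a.data >= lo) & (a.data <= hi)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _make(out_data, (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _make(a.data * mask, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    # numerically stable two-branch logistic
    out_data = np.where(
        a.data >= 0,
        1.0 / (1.0 + np.exp(-np.abs(a.data))),
        np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data))),
    )

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accumulate(out_data * (g - dot))

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# reductions / shaping
# ---------------------------------------------------------------------------

def reduce_sum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape))
            return
        axes = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, axes)
        a._accumulate(np.broadcast_to(g, a.shape))

    return _make(out_data, (a,), backward)


def reduce_mean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(reduce_sum(a, axis=axis, keepdims=keepdims), Tensor(1.0 / n))


def reshape(a: Tensor, shape) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.shape))

    return _make(a.data.reshape(shape), (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    inverse = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.transpose(inverse))

    return _make(a.data.transpose(axes), (a,), backward)


def concat(tensors, axis: int) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return _make(out_data, tuple(tensors), backward)


def gather_rows(a: Tensor, indices: np.ndarray) -> Tensor:
    """Select a[i, indices[i]] for each row i of a 2-D tensor."""
    indices = np.asarray(indices, dtype=np.intp)
    rows = np.arange(a.shape[0])
    out_data = a.data[rows, indices]

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.add.at(full, (rows, indices), g)
            a._accumulate(full)

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# linear algebra
# ---------------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product with numpy batching rules (b must be 2-D or match)."""
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.shape))

    return _make(out_data, (a, b), backward)


# ---------------------------------------------------------------------------
# convolution / pooling
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW input, OIHW weights."""
    n, cin, h, wid = x.shape
    cout, cin_w, kh, kw = w.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, weight {cin_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (wid + 2 * padding - kw) // stride + 1

    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]          # (N, Cin, Ho, Wo, kh, kw)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, cin * kh * kw)
    wmat = w.data.reshape(cout, cin * kh * kw)
    out = cols @ wmat.T
    out_data = out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
    if b is not None:
        out_data = out_data + b.data.reshape(1, cout, 1, 1)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
        if w.requires_grad:
            gw = gmat.T @ cols
            w._accumulate(gw.reshape(cout, cin, kh, kw))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = (gmat @ wmat).reshape(n, ho, wo, cin, kh, kw)
            gxp = np.zeros_like(xp)
            for ki in range(kh):
                for kj in range(kw):
                    gxp[:, :, ki:ki + stride * ho:stride,
                        kj:kj + stride * wo:stride] += gcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, backward)


def _adaptive_windows(n_in: int, n_out: int):
    starts = (np.arange(n_out) * n_in) // n_out
    ends = -(-(np.arange(1, n_out + 1) * n_in) // n_out)   # ceil division
    return starts, ends


def adaptive_avg_pool2d(x: Tensor, out_size: tuple[int, int]) -> Tensor:
    """Average pooling to an arbitrary output grid (PyTorch window rule)."""
    n, c, h, w = x.shape
    oh, ow = out_size
    if oh < 1 or ow < 1:
        raise ValueError("output size must be positive")
    if (oh, ow) == (h, w):
        def backward_id(g):
            if x.requires_grad:
                x._accumulate(g)
        return _make(x.data.copy(), (x,), backward_id)

    hs, he = _adaptive_windows(h, oh)
    ws, we = _adaptive_windows(w, ow)
    out_data = np.empty((n, c, oh, ow))
    for i in range(oh):
        for j in range(ow):
            out_data[:, :, i, j] = x.data[:, :, hs[i]:he[i], ws[j]:we[j]].mean(axis=(2, 3))

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        for i in range(oh):
            for j in range(ow):
                area = (he[i] - hs[i]) * (we[j] - ws[j])
                gx[:, :, hs[i]:he[i], ws[j]:we[j]] += (
                    g[:, :, i, j][:, :, None, None] / area
                )
        x._accumulate(gx)

    return _make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# bilinear-descriptor specific operations
# ---------------------------------------------------------------------------

def signed_sqrt(a: Tensor, eps: float = 1e-12) -> Tensor:
    """Elementwise sign(x)·√|x|; gradient regularised at the origin."""
    root = np.sqrt(np.abs(a.data))
    out_data = np.sign(a.data) * root

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * 0.5 / (root + eps))

    return _make(out_data, (a,), backward)


def l2_normalize(a: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    norm = np.sqrt((a.data ** 2).sum(axis=axis, keepdims=True))
    safe = np.maximum(norm, eps)
    out_data = a.data / safe

    def backward(g):
        if a.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accumulate((g - out_data * dot) / safe)

    return _make(out_data, (a,), backward)


def circular_conv_pool(a: Tensor, b: Tensor) -> Tensor:
    """Sum over positions of the circular convolution of two sketch stacks.

    `a` and `b` have shape (N, P, d) — per-position Count Sketches of the two
    streams — and the result is the (N, d) compact bilinear descriptor
    Σ_p  a[·,p,:] ⊛ b[·,p,:], evaluated in the frequency domain.

    The gradient of a circular convolution is a circular correlation, which
    is again evaluated with FFTs.
    """
    if a.shape != b.shape:
        raise ValueError(f"sketch stacks differ in shape: {a.shape} vs {b.shape}")
    d = a.shape[-1]
    fa = np.fft.rfft(a.data, axis=-1)
    fb = np.fft.rfft(b.data, axis=-1)
    out_data = np.fft.irfft(fa * fb, n=d, axis=-1).sum(axis=1)

    def backward(g):
        fg = np.fft.rfft(g, axis=-1)[:, None, :]
        if a.requires_grad:
            a._accumulate(np.fft.irfft(fg * np.conj(fb), n=d, axis=-1))
        if b.requires_grad:
            b._accumulate(np.fft.irfft(fg * np.conj(fa), n=d, axis=-1))

    return _make(out_data, (a, b), backward)
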