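"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the word-recognition network needs:
broadcast arithmetic, matmul, reductions, ReLU, a numerically stable
sigmoid, 2-D convolution with valid-time / same-frequency boundary
handling, strided weighted-average pooling, dropout and a fused
softmax cross-entropy loss.  Gradients are accumulated on a tape and
released by topological traversal from the loss node.

All array data is kept in float32 by default; gradient correctness is
checked against central differences in the test suite.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # keep ndarray.__mul__ from hijacking

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=DTYPE)
        self.grad += np.asarray(g, dtype=self.grad.dtype)

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data, dtype=DTYPE)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(grad)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _make(self.data / other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g / other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(
                        _unbroadcast(-g * self.data / other.data**2, other.shape))
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = _make(self.data**p, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(
                g * p * self.data**(p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _make(self.data @ other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                g = np.asarray(g, dtype=DTYPE)
                if self.requires_grad:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                    self._accumulate(_unbroadcast(ga, self.shape))
                if other.requires_grad:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                    other._accumulate(_unbroadcast(gb, other.shape))
            out._backward = bw
        return out

    # -- reductions / reshaping ----------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def bw(g):
                g = np.asarray(g)
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = _make(self.data.reshape(*shape), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    # -- nonlinearities -------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = _make(np.where(mask, self.data, 0.0), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    def exp(self):
        out = _make(np.exp(self.data), (self,))
        if out.requires_grad:
            e = out.data   # capture the array, not the Tensor (no ref cycle)
            out._backward = lambda g: self._accumulate(g * e)
        return out

    def sigmoid(self):
        # log-sum-exp-safe logistic: never overflows for large |x|
        x = self.data
        s = np.empty_like(x)
        pos = x >= 0
        s[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        s[~pos] = ex / (1.0 + ex)
        out = _make(s, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def sqrt(self):
        return self**0.5


def _make(data, parents) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = parents
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------
# network primitives
# ---------------------------------------------------------------------

def conv2d_valid_same(x: Tensor, w: Tensor) -> Tensor:
    """2-D convolution: 'same' (zero-pad) on the frequency axis, 'valid'
    on the time axis, stride 1, no bias.

    x: (B, C_in, F, T), w: (C_out, C_in, n_f, n_t) -> (B, C_out, F, T - n_t + 1)
    """
    B, Cin, F, T = x.shape
    Cout, Cin_w, nf, nt = w.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, kernel {Cin_w}")
    if T < nt:
        raise ValueError(f"time axis ({T}) shorter than kernel ({nt})")
    pl = (nf - 1) // 2  # left-biased 'same' padding for odd/even kernels
    pr = nf - 1 - pl
    To = T - nt + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr), (0, 0)))
    # im2col: one large sgemm instead of nf*nt small contractions
    win = np.lib.stride_tricks.sliding_window_view(xp, (nf, nt),
                                                   axis=(2, 3))
    # (B, Cin, F, To, nf, nt) -> (B, F, To, Cin, nf, nt) -> (B*F*To, K)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B * F * To, Cin * nf * nt)
    wmat = w.data.reshape(Cout, Cin * nf * nt)
    y = (cols @ wmat.T).reshape(B, F, To, Cout).transpose(0, 3, 1, 2)
    out = _make(np.ascontiguousarray(y), (x, w))
    if out.requires_grad:
        def bw(g):
            g2 = np.ascontiguousarray(
                np.asarray(g, dtype=DTYPE).transpose(0, 2, 3, 1)).reshape(
                B * F * To, Cout)
            if w.requires_grad:
                w._accumulate((g2.T @ cols).reshape(w.shape))
            if x.requires_grad:
                # scatter grad back through the kernel shifts
                gcol = (g2 @ wmat).reshape(B, F, To, Cin, nf, nt)
                gxp = np.zeros_like(xp)
                for i in range(nf):
                    for j in range(nt):
                        gxp[:, :, i:i + F, j:j + To] += (
                            gcol[:, :, :, :, i, j].transpose(0, 3, 1, 2))
                x._accumulate(gxp[:, :, pl:pl + F, :])
        out._backward = bw
    return out


def hann_pool2d(x: Tensor, kernel: np.ndarray, sf: int, st: int) -> Tensor:
    """Weighted-average pooling: strided per-channel 2-D convolution with a
    fixed unit-sum kernel (no padding).

    x: (B, C, F, T); kernel: (h_f, h_t) -> (B, C, (F-h_f)//sf+1, (T-h_t)//st+1)
    """
    B, C, F, T = x.shape
    hf, ht = kernel.shape
    if hf > F or ht > T:
        raise ValueError(f"pooling kernel {kernel.shape} larger than input "
                         f"({F}, {T})")
    Fo = (F - hf) // sf + 1
    To = (T - ht) // st + 1
    y = np.zeros((B, C, Fo, To), dtype=DTYPE)
    for i in range(hf):
        for j in range(ht):
            y += kernel[i, j] * x.data[:, :, i:i + sf * Fo:sf, j:j + st * To:st]
    out = _make(y, (x,))
    if out.requires_grad:
        def bw(g):
            gx = np.zeros_like(x.data, dtype=DTYPE)
            for i in range(hf):
                for j in range(ht):
                    gx[:, :, i:i + sf * Fo:sf, j:j + st * To:st] += kernel[i, j] * g
            x._accumulate(gx)
        out._backward = bw
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout: survivors scaled by 1/(1-p); identity at inference."""
    if not training or p == 0.0:
        return x
    mask = (rng.random(x.shape) >= p).astype(DTYPE) / (1.0 - p)
    out = _make(x.data * mask, (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(g * mask)
    return out


def softmax(logits: np.ndarray, axis=-1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy. logits: (B, V); labels: (B,) int."""
    B = logits.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    loss = (lse - z[np.arange(B), labels]).mean()
    out = _make(np.asarray(loss, dtype=DTYPE), (logits,))
    if out.requires_grad:
        def bw(g):
            p = softmax(logits.data, axis=1)
            p[np.arange(B), labels] -= 1.0
            logits._accumulate(g * p / B)
        out._backward = bw
    return out
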