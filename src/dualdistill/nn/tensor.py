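"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tensor engine: enough primitives (elementwise
arithmetic, matmul, reductions, indexing, 3-D convolution, axis
resampling) to express and train staged video classifiers with the
distillation objectives in this package.  Gradients are accumulated on
every node that requires them, so intermediate activations (needed for
Grad-CAM) keep their gradients after ``backward``.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv3d",
    "interp_axis",
    "log_softmax",
    "softmax",
    "cross_entropy",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An n-d array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[], None] | None = None,
    ):
        if isinstance(data, Tensor):  # pragma: no cover - convenience
            data = data.data
        self.data = np.asarray(data)
        if self.data.dtype.kind not in "fc":
            self.data = self.data.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- graph plumbing ------------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # copy: closures may hand us views of a child's gradient buffer
            self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def requires_grad_(self, flag: bool = True) -> "Tensor":
        self.requires_grad = flag
        return self

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(
            self.data + other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def _bwd():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.shape))

        out._backward = _bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(
            self.data * other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def _bwd():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = _bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) * self**-1.0

    def __pow__(self, exponent: float) -> "Tensor":
        exponent = float(exponent)
        out = Tensor(
            self.data**exponent,
            requires_grad=self.requires_grad,
            _parents=(self,),
        )

        def _bwd():
            if self.requires_grad:
                self._accumulate(out.grad * exponent * self.data ** (exponent - 1.0))

        out._backward = _bwd
        return out

    def sqrt(self, eps: float = 0.0) -> "Tensor":
        """Square root; ``eps`` guards the gradient at zero."""
        out = Tensor(np.sqrt(self.data), requires_grad=self.requires_grad, _parents=(self,))

        def _bwd():
            if self.requires_grad:
                denom = 2.0 * np.maximum(out.data, eps if eps > 0 else np.finfo(out.data.dtype).tiny)
                self._accumulate(out.grad / denom)

        out._backward = _bwd
        return out

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), requires_grad=self.requires_grad, _parents=(self,))

        def _bwd():
            if self.requires_grad:
                self._accumulate(out.grad * out.data)

        out._backward = _bwd
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad, _parents=(self,))

        def _bwd():
            if self.requires_grad:
                self._accumulate(out.grad / self.data)

        out._backward = _bwd
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), requires_grad=self.requires_grad, _parents=(self,))

        def _bwd():
            if self.requires_grad:
                self._accumulate(out.grad * (self.data > 0))

        out._backward = _bwd
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, requires_grad=self.requires_grad, _parents=(self,))

        def _bwd():
            if self.requires_grad:
                self._accumulate(out.grad * s * (1.0 - s))

        out._backward = _bwd
        return out

    # -- shaping -------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), requires_grad=self.requires_grad, _parents=(self,))

        def _bwd():
            if self.requires_grad:
                self._accumulate(out.grad.reshape(self.shape))

        out._backward = _bwd
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        axes = axes or tuple(range(self.ndim))[::-1]
        out = Tensor(self.data.transpose(axes), requires_grad=self.requires_grad, _parents=(self,))
        inverse = np.argsort(axes)

        def _bwd():
            if self.requires_grad:
                self._accumulate(out.grad.transpose(inverse))

        out._backward = _bwd
        return out

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], requires_grad=self.requires_grad, _parents=(self,))

        def _bwd():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accumulate(g)

        out._backward = _bwd
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            requires_grad=self.requires_grad,
            _parents=(self,),
        )

        def _bwd():
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = _bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        idx = np.argmax(self.data, axis=axis)
        val = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        if not keepdims:
            val = np.squeeze(val, axis=axis)
        out = Tensor(val, requires_grad=self.requires_grad, _parents=(self,))

        def _bwd():
            if not self.requires_grad:
                return
            g = out.grad
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), g, axis=axis)
            self._accumulate(full)

        out._backward = _bwd
        return out

    # -- linear algebra ------------------------------------------------------
    def matmul(self, other: "Tensor") -> "Tensor":
        other = as_tensor(other)
        out = Tensor(
            np.matmul(self.data, other.data),
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def _bwd():
            g = out.grad
            if self.requires_grad:
                if other.ndim == 1:
                    ga = np.multiply.outer(g, other.data)
                else:
                    ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                if self.ndim == 1:
                    gb = np.multiply.outer(self.data, g)
                    gb = gb.reshape(other.shape) if gb.shape != other.shape else gb
                else:
                    gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = _bwd
        return out

    __matmul__ = matmul

    def frobenius_norm(self, eps: float = 1e-12) -> "Tensor":
        """sqrt(sum of squares) over all elements, with a safe gradient at 0."""
        return (self * self).sum().sqrt(eps=eps)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        requires_grad=any(t.requires_grad for t in tensors),
        _parents=tuple(tensors),
    )
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bwd():
        parts = np.split(out.grad, splits, axis=axis)
        for t, g in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(g)

    out._backward = _bwd
    return out


def _triple(v) -> tuple[int, int, int]:
    if isinstance(v, Iterable) and not isinstance(v, str):
        t = tuple(int(x) for x in v)
        if len(t) != 3:
            raise ValueError("expected 3 values for a (t, h, w) triple")
        return t
    return (int(v),) * 3


def conv3d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride=1,
    padding=0,
) -> Tensor:
    """3-D cross-correlation of ``x`` (N, C_in, T, H, W) with ``weight``
    (C_out, C_in, kt, kh, kw).  Zero padding, integer strides."""
    x = as_tensor(x)
    weight = as_tensor(weight)
    st, sh, sw = _triple(stride)
    pt, ph, pw = _triple(padding)
    n, ci, t, h, w = x.shape
    co, ci_w, kt, kh, kw = weight.shape
    if ci != ci_w:
        raise ValueError(f"input has {ci} channels but kernel expects {ci_w}")
    to = (t + 2 * pt - kt) // st + 1
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (w + 2 * pw - kw) // sw + 1
    if min(to, ho, wo) < 1:
        raise ValueError("kernel larger than padded input")

    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
    v = to * ho * wo
    k = kt * kh * kw
    # im2col: one strided gather per kernel offset, then a single GEMM;
    # the column buffer is kept alive for the backward pass
    cols = np.empty((n, k, ci, to, ho, wo), dtype=x.data.dtype)
    slices = []
    for dt in range(kt):
        for dh in range(kh):
            for dw in range(kw):
                sl = (
                    slice(None),
                    slice(None),
                    slice(dt, dt + st * to, st),
                    slice(dh, dh + sh * ho, sh),
                    slice(dw, dw + sw * wo, sw),
                )
                slices.append(sl)
                cols[:, len(slices) - 1] = xp[sl]
    cols_flat = cols.reshape(n, k * ci, v)
    # weight (Co, Ci, kt, kh, kw) -> (Co, k*Ci) matching the column layout
    w2 = np.ascontiguousarray(weight.data.transpose(0, 2, 3, 4, 1)).reshape(co, k * ci)
    out_data = np.matmul(w2, cols_flat).reshape(n, co, to, ho, wo)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, co, 1, 1, 1)

    parents = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(
        out_data,
        requires_grad=any(p.requires_grad for p in parents),
        _parents=parents,
    )

    def _bwd():
        g = out.grad.reshape(n, co, v)
        if bias is not None and bias.requires_grad:
            bias._accumulate(out.grad.sum(axis=(0, 2, 3, 4)))
        if weight.requires_grad:
            # (N,Co,V) x (N,V,kCi) summed over N -> (Co, k*Ci); batched matmul
            # hands the transposed view straight to BLAS (no tensordot copy)
            gw2 = np.matmul(g, cols_flat.transpose(0, 2, 1)).sum(axis=0)
            gw = gw2.reshape(co, kt, kh, kw, ci).transpose(0, 4, 1, 2, 3)
            weight._accumulate(np.ascontiguousarray(gw))
        if x.requires_grad:
            gcols = np.matmul(w2.T, g).reshape(n, k, ci, to, ho, wo)
            gxp = np.zeros_like(xp)
            for ki, sl in enumerate(slices):
                gxp[sl] += gcols[:, ki]
            x._accumulate(gxp[:, :, pt : pt + t, ph : ph + h, pw : pw + w])

    out._backward = _bwd
    return out


def interp_axis(x: Tensor, matrix: np.ndarray, axis: int) -> Tensor:
    """Apply a fixed resampling matrix (n_out, n_in) along ``axis``.

    Linear in ``x``, so the backward pass is the transposed matrix.
    """
    x = as_tensor(x)
    m = np.asarray(matrix, dtype=x.data.dtype)
    data = np.moveaxis(np.tensordot(m, np.moveaxis(x.data, axis, 0), axes=([1], [0])), 0, axis)
    out = Tensor(data, requires_grad=x.requires_grad, _parents=(x,))

    def _bwd():
        if x.requires_grad:
            g = np.moveaxis(np.tensordot(m.T, np.moveaxis(out.grad, axis, 0), axes=([1], [0])), 0, axis)
            x._accumulate(g)

    out._backward = _bwd
    return out


def log_softmax(logits: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax (shift by a detached max)."""
    shift = Tensor(np.max(logits.data, axis=axis, keepdims=True))
    z = logits - shift
    lse = z.exp().sum(axis=axis, keepdims=True).log()
    return z - lse


def softmax(logits: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(logits, axis=axis).exp()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under ``logits`` (N, n_classes)."""
    labels = np.asarray(labels)
    if labels.ndim != 1 or logits.ndim != 2:
        raise ValueError("expected logits (N, C) and labels (N,)")
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= logits.shape[1]:
        raise ValueError(
            f"labels must lie in [0, {logits.shape[1] - 1}]"
        )
    lp = log_softmax(logits, axis=1)
    picked = lp[np.arange(len(labels)), labels]
    return -picked.mean()
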