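"""Reverse-mode automatic differentiation on numpy arrays.

This is the numerical core the segmentation network is built on: a small
define-by-run tape. Every operation returns a new :class:`Tensor` whose
``_backward`` closure scatters the incoming gradient to its parents.
Convolutions are evaluated by im2col/GEMM with the patch matrix rebuilt
during the backward pass, so memory stays proportional to the activations
rather than to the unrolled patches.

Only the operations the network needs are provided; all of them support
arbitrary leading batch dimensions where that is meaningful.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "as_tensor",
    "concatenate",
    "conv2d",
    "conv_transpose2d",
    "exp",
    "log",
    "relu",
    "sigmoid",
    "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64 if not isinstance(data, np.ndarray) else data.dtype)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # ------------------------------------------------------------------ basics
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar")
            grad = np.ones_like(self.data)
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
            for parent in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate gradients: leaves keep theirs
                node.grad = None

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = _op(self.data + other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = _op(self.data * other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __truediv__(self, other) -> "Tensor":
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        exponent = float(exponent)
        out = _op(self.data ** exponent, (self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0))

        out._backward = backward
        return out

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = _op(self.data @ other.data, (self, other))

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = backward
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = _op(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(count))

    def max(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.max(axis=axis, keepdims=keepdims)
        out = _op(data, (self,))

        def backward(g):
            if not self.requires_grad:
                return
            expanded = data if keepdims or axis is None else np.expand_dims(data, axis)
            gg = g if keepdims or axis is None else np.expand_dims(g, axis)
            mask = (self.data == expanded).astype(self.data.dtype)
            counts = mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
            self._accum(mask * gg / counts)

        out._backward = backward
        return out

    # ----------------------------------------------------------------- shapes
    def reshape(self, shape) -> "Tensor":
        out = _op(self.data.reshape(shape), (self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = backward
        return out

    def transpose(self, axes) -> "Tensor":
        out = _op(self.data.transpose(axes), (self,))
        inverse = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inverse))

        out._backward = backward
        return out

    def clip(self, low: float, high: float) -> "Tensor":
        """Clamp values; the gradient passes through strictly interior entries."""
        out = _op(np.clip(self.data, low, high), (self,))

        def backward(g):
            if self.requires_grad:
                mask = ((self.data >= low) & (self.data <= high)).astype(self.data.dtype)
                self._accum(g * mask)

        out._backward = backward
        return out


class Parameter(Tensor):
    """A leaf tensor updated by an optimizer."""

    __slots__ = ("name",)

    def __init__(self, data, name: str = ""):
        super().__init__(np.asarray(data), requires_grad=True)
        self.name = name


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(np.asarray(value, dtype=np.float64))


def _op(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    return Tensor(data, requires_grad=any(p.requires_grad for p in parents), parents=parents)


# ------------------------------------------------------------------ pointwise
def exp(x: Tensor) -> Tensor:
    data = np.exp(x.data)
    out = _op(data, (x,))

    def backward(g):
        if x.requires_grad:
            x._accum(g * data)

    out._backward = backward
    return out


def log(x: Tensor) -> Tensor:
    out = _op(np.log(x.data), (x,))

    def backward(g):
        if x.requires_grad:
            x._accum(g / x.data)

    out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    out = _op(np.maximum(x.data, 0.0), (x,))

    def backward(g):
        if x.requires_grad:
            x._accum(g * (x.data > 0.0))

    out._backward = backward
    return out


def sigmoid(x: Tensor) -> Tensor:
    data = 1.0 / (1.0 + np.exp(-x.data))
    out = _op(data, (x,))

    def backward(g):
        if x.requires_grad:
            x._accum(g * data * (1.0 - data))

    out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax, fused so only the output is retained."""
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    data = np.exp(shifted)
    data /= data.sum(axis=axis, keepdims=True)
    out = _op(data, (x,))

    def backward(g):
        if x.requires_grad:
            inner = (g * data).sum(axis=axis, keepdims=True)
            x._accum(data * (g - inner))

    out._backward = backward
    return out


def concatenate(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _op(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                index = [slice(None)] * g.ndim
                index[axis] = slice(lo, hi)
                t._accum(g[tuple(index)])

    out._backward = backward
    return out


# --------------------------------------------------------------- convolutions
def _pad_amounts(size: int, kernel: int, stride: int, dilation: int) -> tuple[int, int, int]:
    """(out_size, pad_before, pad_after) for 'same' padding."""
    effective = (kernel - 1) * dilation + 1
    out = -(-size // stride)  # ceil division
    total = max((out - 1) * stride + effective - size, 0)
    return out, total // 2, total - total // 2


def _im2col(xp: np.ndarray, kh: int, kw: int, ho: int, wo: int, stride: int, dilation: int) -> np.ndarray:
    b, _, _, c = xp.shape
    cols = np.empty((b, ho, wo, kh * kw, c), dtype=xp.dtype)
    idx = 0
    for di in range(kh):
        for dj in range(kw):
            r0, c0 = di * dilation, dj * dilation
            cols[:, :, :, idx, :] = xp[
                :, r0 : r0 + (ho - 1) * stride + 1 : stride, c0 : c0 + (wo - 1) * stride + 1 : stride, :
            ]
            idx += 1
    return cols.reshape(b, ho, wo, kh * kw * c)


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    dilation: int = 1,
    padding: str = "same",
) -> Tensor:
    """2-D convolution in NHWC layout; ``weight`` is (kh, kw, c_in, c_out)."""
    b, h, w, c = x.data.shape
    kh, kw, cin, cout = weight.data.shape
    if cin != c:
        raise ValueError(f"conv2d channel mismatch: input has {c}, kernel expects {cin}")
    if padding == "same":
        ho, pt, pb = _pad_amounts(h, kh, stride, dilation)
        wo, pl, pr = _pad_amounts(w, kw, stride, dilation)
    elif padding == "valid":
        ho = (h - (kh - 1) * dilation - 1) // stride + 1
        wo = (w - (kw - 1) * dilation - 1) // stride + 1
        pt = pb = pl = pr = 0
    else:  # pragma: no cover - guarded by callers
        raise ValueError(f"unknown padding mode {padding!r}")

    def padded() -> np.ndarray:
        if pt or pb or pl or pr:
            return np.pad(x.data, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        return x.data

    wmat = weight.data.reshape(kh * kw * c, cout)
    cols = _im2col(padded(), kh, kw, ho, wo, stride, dilation)
    data = cols.reshape(-1, kh * kw * c) @ wmat
    data = data.reshape(b, ho, wo, cout)
    if bias is not None:
        data = data + bias.data
    del cols  # rebuilt on demand in backward
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = _op(data, parents)

    def backward(g):
        gmat = g.reshape(-1, cout)
        if weight.requires_grad:
            cols_b = _im2col(padded(), kh, kw, ho, wo, stride, dilation)
            gw = cols_b.reshape(-1, kh * kw * c).T @ gmat
            weight._accum(gw.reshape(weight.data.shape))
            del cols_b
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            dcols = (gmat @ wmat.T).reshape(b, ho, wo, kh * kw, c)
            dxp = np.zeros((b, h + pt + pb, w + pl + pr, c), dtype=x.data.dtype)
            idx = 0
            for di in range(kh):
                for dj in range(kw):
                    r0, c0 = di * dilation, dj * dilation
                    dxp[
                        :, r0 : r0 + (ho - 1) * stride + 1 : stride, c0 : c0 + (wo - 1) * stride + 1 : stride, :
                    ] += dcols[:, :, :, idx, :]
                    idx += 1
            x._accum(dxp[:, pt : pt + h, pl : pl + w, :])

    out._backward = backward
    return out


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Transposed convolution with a 2x2 kernel and stride 2 (exact doubling)."""
    b, h, w, cin = x.data.shape
    kh, kw, wcin, cout = weight.data.shape
    if (kh, kw) != (2, 2):
        raise ValueError("conv_transpose2d supports 2x2 kernels with stride 2")
    if wcin != cin:
        raise ValueError(f"conv_transpose2d channel mismatch: input has {cin}, kernel expects {wcin}")
    data = np.empty((b, 2 * h, 2 * w, cout), dtype=x.data.dtype)
    flat = x.data.reshape(-1, cin)
    for di in (0, 1):
        for dj in (0, 1):
            data[:, di::2, dj::2, :] = (flat @ weight.data[di, dj]).reshape(b, h, w, cout)
    if bias is not None:
        data += bias.data
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = _op(data, parents)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 1, 2)))
        gx = np.zeros_like(x.data) if x.requires_grad else None
        for di in (0, 1):
            for dj in (0, 1):
                gslice = g[:, di::2, dj::2, :].reshape(-1, cout)
                if weight.requires_grad:
                    gw = flat.T @ gslice
                    if weight.grad is None:
                        weight.grad = np.zeros_like(weight.data)
                    weight.grad[di, dj] += gw
                if gx is not None:
                    gx += (gslice @ weight.data[di, dj].T).reshape(x.data.shape)
        if gx is not None:
            x._accum(gx)

    out._backward = backward
    return out
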