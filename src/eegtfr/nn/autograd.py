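"""A small reverse-mode automatic-differentiation engine on NumPy arrays.

Only the operations the classifier architectures need are provided:
broadcasting arithmetic, matmul (2-D and batched), reshape/transpose,
reductions, the activation functions used by the CNN families
(ReLU/sigmoid/SiLU/hard-swish/hard-sigmoid), grouped 2-D convolution via
im2col, max pooling, dropout, and a fused softmax cross-entropy loss.
Gradients accumulate into ``Tensor.grad`` after calling ``backward()``
on a scalar.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
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
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, grad):
        grad = grad.astype(np.float32, copy=False)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other.pow(-1.0)

    def pow(self, p: float) -> "Tensor":
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        out._backward = bwd
        return out

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.transpose(*inv))

        out._backward = bwd
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- matmul -----------------------------------------------------------
    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = bwd
        return out

    __matmul__ = matmul

    # -- activations ------------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = bwd
        return out

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * y * (1 - y))

        out._backward = bwd
        return out

    def silu(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * s, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (s * (1 + self.data * (1 - s))))

        out._backward = bwd
        return out

    def hardsigmoid(self) -> "Tensor":
        y = np.clip(self.data / 6.0 + 0.5, 0.0, 1.0)
        out = Tensor(y, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                mask = (self.data > -3) & (self.data < 3)
                self._accumulate(g * mask / 6.0)

        out._backward = bwd
        return out

    def hardswish(self) -> "Tensor":
        inner = np.clip(self.data + 3.0, 0.0, 6.0)
        out = Tensor(self.data * inner / 6.0, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                d = np.where(self.data <= -3, 0.0,
                             np.where(self.data >= 3, 1.0,
                                      (2 * self.data + 3) / 6.0))
                self._accumulate(g * d)

        out._backward = bwd
        return out

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * y)

        out._backward = bwd
        return out


# -- convolution / pooling ----------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (x.shape[2] - kh) // stride + 1
    ow = (x.shape[3] - kw) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    cols = windows[:, :, ::stride, ::stride]        # b,c,oh,ow,kh,kw
    return np.ascontiguousarray(cols), oh, ow


def _col2im(cols: np.ndarray, x_shape: tuple, kh: int, kw: int, stride: int, pad: int):
    b, c, h, w = x_shape
    out = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    oh, ow = cols.shape[2], cols.shape[3]
    for i in range(kh):
        for j in range(kw):
            out[:, :, i:i + oh * stride:stride, j:j + ow * stride:stride] += cols[:, :, :, :, i, j]
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """Grouped 2-D convolution (NCHW; depthwise when groups == channels)."""
    b, c, _, _ = x.shape
    cout, cin_g, kh, kw = weight.shape
    assert c == cin_g * groups, "channel/group mismatch"
    cout_g = cout // groups

    cols, oh, ow = _im2col(x.data, kh, kw, stride, padding)
    # b,c,oh,ow,kh,kw -> b,g,(cin_g*kh*kw),(oh*ow)
    cols_g = cols.reshape(b, groups, cin_g, oh, ow, kh * kw)
    cols_g = cols_g.transpose(0, 1, 2, 5, 3, 4).reshape(b, groups, cin_g * kh * kw, oh * ow)
    w_g = weight.data.reshape(groups, cout_g, cin_g * kh * kw)

    out_data = np.einsum("gok,bgkp->bgop", w_g, cols_g, optimize=True)
    out_data = out_data.reshape(b, cout, oh, ow)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, cout, 1, 1)

    req = x.requires_grad or weight.requires_grad or (bias is not None and bias.requires_grad)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data, req, parents)

    def bwd(g):
        gg = g.reshape(b, groups, cout_g, oh * ow)
        if weight.requires_grad:
            gw = np.einsum("bgop,bgkp->gok", gg, cols_g, optimize=True)
            weight._accumulate(gw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.einsum("gok,bgop->bgkp", w_g, gg, optimize=True)
            gcols = gcols.reshape(b, groups, cin_g, kh * kw, oh, ow)
            gcols = gcols.transpose(0, 1, 2, 4, 5, 3).reshape(b, c, oh, ow, kh, kw)
            x._accumulate(_col2im(gcols, x.data.shape, kh, kw, stride, padding))

    out._backward = bwd
    return out


def maxpool2d(x: Tensor, kernel: int = 2, stride: int | None = None,
              padding: int = 0) -> Tensor:
    stride = stride or kernel
    if padding:
        neg = np.finfo(np.float32).min
        xdata = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                       constant_values=neg)
    else:
        xdata = x.data
    b, c, _, _ = xdata.shape
    windows = np.lib.stride_tricks.sliding_window_view(xdata, (kernel, kernel), axis=(2, 3))
    oh = (xdata.shape[2] - kernel) // stride + 1
    ow = (xdata.shape[3] - kernel) // stride + 1
    cols = windows[:, :, ::stride, ::stride][:, :, :oh, :ow].reshape(b, c, oh, ow, kernel * kernel)
    amax = cols.argmax(axis=-1)
    out_data = np.take_along_axis(cols, amax[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, x.requires_grad, (x,))

    def bwd(g):
        if not x.requires_grad:
            return
        gcols = np.zeros_like(cols)
        np.put_along_axis(gcols, amax[..., None], g[..., None], axis=-1)
        gcols = gcols.reshape(b, c, oh, ow, kernel, kernel)
        gx = _col2im(gcols, xdata.shape, kernel, kernel, stride, 0)
        if padding:
            gx = gx[:, :, padding:-padding, padding:-padding]
        x._accumulate(gx)

    out._backward = bwd
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool = True) -> Tensor:
    if not training or p <= 0:
        return x
    mask = (rng.random(x.shape) >= p).astype(np.float32) / (1 - p)
    return x * Tensor(mask)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, x.requires_grad, (x,))

    def bwd(g):
        if x.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accumulate(y * (g - dot))

    out._backward = bwd
    return out


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer class targets; fused stable backward."""
    targets = np.asarray(targets)
    n = logits.shape[0]
    shifted = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    logp = shifted - logsumexp
    loss = -logp[np.arange(n), targets].mean()
    out = Tensor(loss, logits.requires_grad, (logits,))

    def bwd(g):
        if logits.requires_grad:
            p = np.exp(logp)
            p[np.arange(n), targets] -= 1.0
            logits._accumulate(g * p / n)

    out._backward = bwd
    return out
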