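"""Neural-network modules built on the autodiff engine.

The Module protocol mirrors the conventional train/eval split: batch
normalisation uses batch statistics and updates running estimates in
training mode, and dropout is active only in training mode.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: parameter discovery, mode switching, state copy."""

    training: bool = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self):
        seen = set()
        for mod in self.modules():
            for v in mod.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad and id(v) not in seen:
                    seen.add(id(v))
                    yield v

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self):
        """All learnable parameters plus running statistics, in a stable order."""
        arrays = list(self.parameters())
        for mod in self.modules():
            for name in ("running_mean", "running_var"):
                v = mod.__dict__.get(name)
                if isinstance(v, np.ndarray):
                    arrays.append(v)
        return arrays

    def get_state(self):
        return [np.array(a.data if isinstance(a, Tensor) else a) for a in self.state_arrays()]

    def set_state(self, state):
        arrays = self.state_arrays()
        if len(state) != len(arrays):
            raise ValueError("state length mismatch")
        for a, s in zip(arrays, state):
            if isinstance(a, Tensor):
                a.data = np.array(s, dtype=np.float32)
            else:
                a[...] = s

    def __call__(self, x):
        return self.forward(x)


def _kaiming(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, rng, cin, cout, kernel, stride=1, padding=0, groups=1, bias=False):
        fan_in = cin // groups * kernel * kernel
        self.weight = Tensor(_kaiming(rng, (cout, cin // groups, kernel, kernel), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class Linear(Module):
    def __init__(self, rng, nin, nout):
        bound = 1.0 / np.sqrt(nin)
        self.weight = Tensor(rng.uniform(-bound, bound, (nin, nout)).astype(np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(nout, np.float32), requires_grad=True)

    def forward(self, x):
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    def __init__(self, num_features, eps=1e-5, momentum=0.1):
        self.gamma = Tensor(np.ones(num_features, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, np.float32), requires_grad=True)
        self.running_mean = np.zeros(num_features, np.float32)
        self.running_var = np.ones(num_features, np.float32)
        self.eps, self.momentum = eps, momentum

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            inv = (var + self.eps).pow(-0.5)
            xn = centered * inv
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            inv = 1.0 / np.sqrt(self.running_var.reshape(1, -1, 1, 1) + self.eps)
            xn = (x - Tensor(mu)) * Tensor(inv)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xn * g + b


class LayerNorm(Module):
    def __init__(self, dim, eps=1e-5):
        self.gamma = Tensor(np.ones(dim, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, np.float32), requires_grad=True)
        self.eps = eps

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        xn = centered * (var + self.eps).pow(-0.5)
        return xn * self.gamma + self.beta


class Activation(Module):
    def __init__(self, kind):
        self.kind = kind

    def forward(self, x):
        return getattr(x, self.kind)()


class MaxPool2d(Module):
    def __init__(self, kernel, stride=None, padding=0):
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return ag.maxpool2d(x, self.kernel, self.stride, self.padding)


class GlobalAvgPool(Module):
    def forward(self, x):
        return x.mean(axis=(2, 3))


class Dropout(Module):
    def __init__(self, p, rng):
        self.p = p
        self.rng = rng

    def forward(self, x):
        return ag.dropout(x, self.p, self.rng, self.training)


class Sequential(Module):
    def __init__(self, *mods):
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class MultiHeadSelfAttention(Module):
    """Standard scaled-dot-product self-attention over token sequences."""

    def __init__(self, rng, dim, n_heads, dropout_p=0.0):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(rng, dim, 3 * dim)
        self.proj = Linear(rng, dim, dim)
        self.drop = Dropout(dropout_p, rng)

    def forward(self, x):                      # x: (B, N, D)
        b, n, d = x.shape
        h, hd = self.n_heads, self.head_dim
        qkv = self.qkv(x).reshape(b, n, 3, h, hd).transpose(2, 0, 3, 1, 4)
        qf = _slice0(qkv, 0).reshape(b * h, n, hd)
        kf = _slice0(qkv, 1).reshape(b * h, n, hd)
        vf = _slice0(qkv, 2).reshape(b * h, n, hd)
        att = (qf @ kf.transpose(0, 2, 1)) * (1.0 / np.sqrt(hd))
        att = ag.softmax(att, axis=-1)
        out = (att @ vf).reshape(b, h, n, hd).transpose(0, 2, 1, 3).reshape(b, n, d)
        return self.drop(self.proj(out))


def _slice0(t: Tensor, idx: int) -> Tensor:
    """Differentiable selection of index ``idx`` along axis 0."""
    out = Tensor(t.data[idx], t.requires_grad, (t,))

    def bwd(g):
        if t.requires_grad:
            full = np.zeros_like(t.data)
            full[idx] = g
            t._accumulate(full)

    out._backward = bwd
    return out


class TransformerBlock(Module):
    """Pre-norm ViT encoder block: MHSA + MLP, each with a residual path."""

    def __init__(self, rng, dim, n_heads, mlp_ratio=4, dropout_p=0.1):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(rng, dim, n_heads, dropout_p)
        self.norm2 = LayerNorm(dim)
        inner = mlp_ratio * dim
        self.fc1 = Linear(rng, dim, inner)
        self.fc2 = Linear(rng, inner, dim)
        self.drop = Dropout(dropout_p, rng)
        self.mlp_inner_width = inner

    def forward(self, x):
        x = x + self.attn(self.norm1(x))
        h = self.drop(self.fc1(self.norm2(x)).relu())
        return x + self.drop(self.fc2(h))
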