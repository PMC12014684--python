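"""Minimal reverse-mode autodiff engine on numpy arrays.

Only what the detector needs: broadcasting elementwise arithmetic,
reductions, slicing/concat, grouped 2-D convolution (im2col), nearest
upsampling, batch normalization, and an SGD optimizer with parameter
groups. Arrays keep whatever float dtype they come in with; training
code uses float32, gradient-check tests use float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "ModuleList",
    "Conv2d",
    "BatchNorm2d",
    "HardSwish",
    "Sequential",
    "SGD",
    "concat",
    "stack_sum",
    "conv2d_forward",
    "conv_output_hw",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype.kind != "f":
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # -- graph plumbing ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(p for p in parents if p.requires_grad) if out.requires_grad else ()
        out._backward = backward if out.requires_grad else None
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad += g

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- elementwise arithmetic ---------------------------------------
    def _coerce(self, other):
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other
        out = Tensor._make(a.data + b.data, (a, b), None)
        if out.requires_grad:
            def bwd(g):
                if a.requires_grad:
                    a._accum(_unbroadcast(g, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(g, b.data.shape))
            out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        a = self
        out = Tensor._make(-a.data, (a,), None)
        if out.requires_grad:
            out._backward = lambda g: a._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other
        out = Tensor._make(a.data * b.data, (a, b), None)
        if out.requires_grad:
            def bwd(g):
                if a.requires_grad:
                    a._accum(_unbroadcast(g * b.data, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(g * a.data, b.data.shape))
            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self, other
        out = Tensor._make(a.data / b.data, (a, b), None)
        if out.requires_grad:
            def bwd(g):
                if a.requires_grad:
                    a._accum(_unbroadcast(g / b.data, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))
            out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, k):
        assert isinstance(k, (int, float))
        a = self
        out = Tensor._make(a.data ** k, (a,), None)
        if out.requires_grad:
            out._backward = lambda g: a._accum(g * k * a.data ** (k - 1))
        return out

    # -- unary functions ----------------------------------------------
    def exp(self):
        a = self
        ed = np.exp(a.data)
        out = Tensor._make(ed, (a,), None)
        if out.requires_grad:
            out._backward = lambda g: a._accum(g * ed)
        return out

    def log(self):
        a = self
        out = Tensor._make(np.log(a.data), (a,), None)
        if out.requires_grad:
            out._backward = lambda g: a._accum(g / a.data)
        return out

    def sqrt(self):
        a = self
        sd = np.sqrt(a.data)
        out = Tensor._make(sd, (a,), None)
        if out.requires_grad:
            out._backward = lambda g: a._accum(g * 0.5 / sd)
        return out

    def atan(self):
        a = self
        out = Tensor._make(np.arctan(a.data), (a,), None)
        if out.requires_grad:
            out._backward = lambda g: a._accum(g / (1.0 + a.data * a.data))
        return out

    def sigmoid(self):
        a = self
        sd = 1.0 / (1.0 + np.exp(-a.data))
        out = Tensor._make(sd, (a,), None)
        if out.requires_grad:
            out._backward = lambda g: a._accum(g * sd * (1.0 - sd))
        return out

    def hardswish(self):
        a = self
        inner = np.clip(a.data + 3.0, 0.0, 6.0)
        out = Tensor._make(a.data * (inner / 6.0), (a,), None)
        if out.requires_grad:
            # derivative: 0 for x<=-3, (2x+3)/6 for -3<x<3, 1 for x>=3
            def bwd(g):
                d = np.where(a.data <= -3.0, 0.0,
                             np.where(a.data >= 3.0, 1.0, (2.0 * a.data + 3.0) / 6.0))
                a._accum(g * d.astype(g.dtype))
            out._backward = bwd
        return out

    def relu(self):
        a = self
        out = Tensor._make(np.maximum(a.data, 0.0), (a,), None)
        if out.requires_grad:
            out._backward = lambda g: a._accum(g * (a.data > 0.0))
        return out

    def clip(self, lo, hi):
        a = self
        out = Tensor._make(np.clip(a.data, lo, hi), (a,), None)
        if out.requires_grad:
            mask = (a.data > lo) & (a.data < hi)
            out._backward = lambda g: a._accum(g * mask)
        return out

    def maximum(self, other):
        other = self._coerce(other)
        a, b = self, other
        out = Tensor._make(np.maximum(a.data, b.data), (a, b), None)
        if out.requires_grad:
            def bwd(g):
                m = a.data >= b.data
                if a.requires_grad:
                    a._accum(_unbroadcast(g * m, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(g * ~m, b.data.shape))
            out._backward = bwd
        return out

    def minimum(self, other):
        other = self._coerce(other)
        a, b = self, other
        out = Tensor._make(np.minimum(a.data, b.data), (a, b), None)
        if out.requires_grad:
            def bwd(g):
                m = a.data <= b.data
                if a.requires_grad:
                    a._accum(_unbroadcast(g * m, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(g * ~m, b.data.shape))
            out._backward = bwd
        return out

    # -- reductions / reshapes ----------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        out = Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), None)
        if out.requires_grad:
            def bwd(g):
                gg = g
                if not keepdims and axis is not None:
                    ax = axis if isinstance(axis, tuple) else (axis,)
                    gg = np.expand_dims(g, ax)
                a._accum(np.broadcast_to(gg, a.data.shape).astype(a.data.dtype))
            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[i] for i in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor._make(a.data.reshape(shape), (a,), None)
        if out.requires_grad:
            out._backward = lambda g: a._accum(g.reshape(a.data.shape))
        return out

    def transpose(self, *axes):
        a = self
        out = Tensor._make(a.data.transpose(axes), (a,), None)
        if out.requires_grad:
            inv = np.argsort(axes)
            out._backward = lambda g: a._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        a = self
        out = Tensor._make(a.data[idx], (a,), None)
        if out.requires_grad:
            def bwd(g):
                gx = np.zeros_like(a.data)
                np.add.at(gx, idx, g)
                a._accum(gx)
            out._backward = bwd
        return out

    def softmax(self, axis=-1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis=-1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()

    # -- spatial ops ---------------------------------------------------
    def conv2d(self, w: "Tensor", b: "Tensor | None", stride: int = 1,
               padding: int = 0, groups: int = 1) -> "Tensor":
        x = self
        out_d, cols, meta = _conv2d_fwd(x.data, w.data, stride, padding, groups)
        if b is not None:
            out_d = out_d + b.data.reshape(1, -1, 1, 1)
        parents = (x, w) if b is None else (x, w, b)
        out = Tensor._make(out_d, parents, None)
        if out.requires_grad:
            def bwd(g):
                gx, gw = _conv2d_bwd(g, x.data, w.data, cols, meta,
                                     need_gx=x.requires_grad, need_gw=w.requires_grad)
                if x.requires_grad:
                    x._accum(gx)
                if w.requires_grad:
                    w._accum(gw)
                if b is not None and b.requires_grad:
                    b._accum(g.sum(axis=(0, 2, 3)))
            out._backward = bwd
        return out

    def upsample_nearest(self, factor: int = 2) -> "Tensor":
        a = self
        out_d = a.data.repeat(factor, axis=2).repeat(factor, axis=3)
        out = Tensor._make(out_d, (a,), None)
        if out.requires_grad:
            f = factor

            def bwd(g):
                n, c, h, w = a.data.shape
                a._accum(g.reshape(n, c, h, f, w, f).sum(axis=(3, 5)))
            out._backward = bwd
        return out


def concat(tensors, axis=0):
    datas = [t.data for t in tensors]
    out = Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), None)
    if out.requires_grad:
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def bwd(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(g[tuple(sl)])
        out._backward = bwd
    return out


def stack_sum(tensors):
    """Sum a list of same-shape tensors."""
    out = tensors[0]
    for t in tensors[1:]:
        out = out + t
    return out


def bce_with_logits(z: Tensor, y: np.ndarray) -> Tensor:
    """Elementwise binary cross entropy on logits; `y` is a constant target."""
    y = np.asarray(y, dtype=z.data.dtype)
    zd = z.data
    loss = np.maximum(zd, 0.0) - zd * y + np.log1p(np.exp(-np.abs(zd)))
    out = Tensor._make(loss, (z,), None)
    if out.requires_grad:
        def bwd(g):
            s = 1.0 / (1.0 + np.exp(-zd))
            z._accum(g * (s - y))
        out._backward = bwd
    return out


# ---------------------------------------------------------------------
# raw convolution kernels (shared by the autograd op and by oracle-free
# functional block application)
# ---------------------------------------------------------------------

def conv_output_hw(h: int, w: int, k: int, stride: int, padding: int):
    return (h + 2 * padding - k) // stride + 1, (w + 2 * padding - k) // stride + 1


def _conv2d_fwd(x, w, stride, padding, groups):
    n, c, h, wd = x.shape
    cout, cg, k, _ = w.shape
    if c % groups or cout % groups or cg != c // groups:
        raise ValueError(
            f"channel mismatch: input {c} channels, weight expects "
            f"{cg}x{groups} (groups={groups}, out={cout})")
    p, s = padding, stride
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
    sw = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    ho, wo = sw.shape[2], sw.shape[3]
    # (n, g, cg, ho, wo, k, k)
    cols = np.ascontiguousarray(sw.reshape(n, groups, cg, ho, wo, k, k))
    wg = w.reshape(groups, cout // groups, cg, k, k)
    out = np.einsum("ngchwkl,gockl->ngohw", cols, wg, optimize=True)
    out = np.ascontiguousarray(out.reshape(n, cout, ho, wo))
    return out, cols, (stride, padding, groups, k, ho, wo)


def _conv2d_bwd(g, x, w, cols, meta, need_gx=True, need_gw=True):
    s, p, groups, k, ho, wo = meta
    n, c, h, wd = x.shape
    cout = w.shape[0]
    cg = c // groups
    gg = g.reshape(n, groups, cout // groups, ho, wo)
    gw = gx = None
    if need_gw:
        gw = np.einsum("ngchwkl,ngohw->gockl", cols, gg, optimize=True)
        gw = gw.reshape(w.shape)
    if need_gx:
        wg = w.reshape(groups, cout // groups, cg, k, k)
        gcols = np.einsum("ngohw,gockl->ngchwkl", gg, wg, optimize=True)
        gcols = gcols.reshape(n, c, ho, wo, k, k)
        gxp = np.zeros((n, c, h + 2 * p, wd + 2 * p), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += gcols[:, :, :, :, i, j]
        gx = gxp[:, :, p:p + h, p:p + wd] if p else gxp
    return gx, gw


def conv2d_forward(x: np.ndarray, w: np.ndarray, stride: int = 1,
                   padding: int = 0, groups: int = 1,
                   bias: np.ndarray | None = None) -> np.ndarray:
    """Plain-numpy grouped convolution (no autograd)."""
    out, _, _ = _conv2d_fwd(np.asarray(x, dtype=float), np.asarray(w, dtype=float),
                            stride, padding, groups)
    if bias is not None:
        out = out + np.asarray(bias, dtype=float).reshape(1, -1, 1, 1)
    return out


# ---------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    def forward(self, *a, **kw):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *a, **kw):
        return self.forward(*a, **kw)

    def _children(self):
        for name, val in self.__dict__.items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, ModuleList):
                for i, m in enumerate(val):
                    yield f"{name}.{i}", m

    def named_modules(self, prefix=""):
        yield prefix, self
        for name, child in self._children():
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_modules(sub)

    def named_parameters(self, prefix=""):
        for name, val in self.__dict__.items():
            if isinstance(val, Parameter):
                yield (f"{prefix}.{name}" if prefix else name), val
        for name, child in self._children():
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_parameters(sub)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self, mode=True):
        for _, m in self.named_modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def num_parameters(self):
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self):
        sd = {f"param:{k}": v.data for k, v in self.named_parameters()}
        for name, m in self.named_modules():
            if isinstance(m, BatchNorm2d):
                sd[f"buffer:{name}.running_mean"] = m.running_mean
                sd[f"buffer:{name}.running_var"] = m.running_var
        return sd

    def load_state_dict(self, sd):
        params = dict(self.named_parameters())
        for key, arr in sd.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = arr.astype(params[name].data.dtype)
            else:
                mod_name, buf = name.rsplit(".", 1)
                mod = dict(self.named_modules())[mod_name]
                setattr(mod, buf, arr.astype(np.float32))


class ModuleList(list):
    pass


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel, stride=1,
                 groups=1, bias=True, padding=None):
        super().__init__()
        if in_channels % groups:
            raise ValueError("in_channels must be divisible by groups")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.groups = groups
        self.padding = kernel // 2 if padding is None else padding
        self.weight = Parameter(np.zeros((out_channels, in_channels // groups, kernel, kernel), np.float32))
        self.bias = Parameter(np.zeros(out_channels, np.float32)) if bias else None

    def reset_parameters(self, rng: np.random.Generator):
        # Kaiming normal, fan-out
        fan_out = self.out_channels * self.kernel * self.kernel // self.groups
        std = np.sqrt(2.0 / fan_out)
        self.weight.data = rng.normal(0.0, std, self.weight.data.shape).astype(np.float32)
        if self.bias is not None:
            self.bias.data[:] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}")
        return x.conv2d(self.weight, self.bias, self.stride, self.padding, self.groups)


class BatchNorm2d(Module):
    def __init__(self, channels, eps=1e-5, momentum=0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, np.float32))
        self.beta = Parameter(np.zeros(channels, np.float32))
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(-1)).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased).astype(np.float32)
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) / (var + self.eps).sqrt()
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class HardSwish(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.hardswish()


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = ModuleList(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


def init_weights(module: Module, seed: int = 0):
    """Deterministic Kaiming-style initialization over module traversal order."""
    rng = np.random.default_rng(seed)
    for _, m in module.named_modules():
        if isinstance(m, Conv2d):
            m.reset_parameters(rng)
        elif isinstance(m, BatchNorm2d):
            m.gamma.data[:] = 1.0
            m.beta.data[:] = 0.0
            m.running_mean[:] = 0.0
            m.running_var[:] = 1.0
    return module


class SGD:
    """SGD with momentum, weight decay and per-group learning rates."""

    def __init__(self, groups):
        # groups: list of dicts {params, lr, momentum, weight_decay}
        self.groups = []
        for g in groups:
            self.groups.append({
                "params": list(g["params"]),
                "lr": g.get("lr", 0.01),
                "momentum": g.get("momentum", 0.9),
                "weight_decay": g.get("weight_decay", 0.0),
                "bufs": [np.zeros_like(p.data) for p in g["params"]],
            })

    def zero_grad(self):
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def step(self):
        for g in self.groups:
            mu, lr, wd = g["momentum"], g["lr"], g["weight_decay"]
            for p, buf in zip(g["params"], g["bufs"]):
                if p.grad is None:
                    continue
                d = p.grad
                if wd:
                    d = d + wd * p.data
                buf *= mu
                buf += d
                p.data -= lr * buf
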