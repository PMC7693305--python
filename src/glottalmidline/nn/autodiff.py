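"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery to express and train the keypoint/segmentation
networks in this package: tensors with a dynamically built graph,
convolutions via im2col, pooling, dense layers, elementwise
nonlinearities and the reductions the losses need.  Sized for
smoke-scale experiments, not for GPU-scale training.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat_channels"]


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing -------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self) -> None:
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
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic -----------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                      other.data.shape))

        return self._make(self.data / other.data, (self, other), bwd)

    def __pow__(self, n: float):
        def bwd(g):
            self._accum(g * n * self.data ** (n - 1))

        return self._make(self.data ** n, (self,), bwd)

    # -- reductions / shape ---------------------------------------------

    def sum(self):
        def bwd(g):
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(self.data.sum(), (self,), bwd)

    def mean(self):
        n = self.data.size

        def bwd(g):
            self._accum(np.broadcast_to(g / n, self.data.shape).copy())

        return self._make(self.data.mean(), (self,), bwd)

    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), bwd)

    # -- elementwise nonlinearities --------------------------------------

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), bwd)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bwd(g):
            self._accum(g * s * (1 - s))

        return self._make(s, (self,), bwd)

    def tanh(self):
        t = np.tanh(self.data)

        def bwd(g):
            self._accum(g * (1 - t ** 2))

        return self._make(t, (self,), bwd)

    def abs(self):
        s = np.sign(self.data)

        def bwd(g):
            self._accum(g * s)

        return self._make(np.abs(self.data), (self,), bwd)

    def logcosh(self):
        """log(cosh(x)), numerically stable; d/dx = tanh(x)."""
        x = self.data
        val = np.abs(x) + np.log1p(np.exp(-2.0 * np.abs(x))) - np.log(2.0)
        t = np.tanh(x)

        def bwd(g):
            self._accum(g * t)

        return self._make(val, (self,), bwd)

    # -- linear algebra ---------------------------------------------------

    def matmul(self, other: "Tensor"):
        other = self._lift(other)

        def bwd(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bwd)

    # -- image ops (N, C, H, W) -------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor", pad: int = 1):
        """Cross-correlation with 'same'-style zero padding.

        x [N,C,H,W] * weight [F,C,kh,kw] + bias [F] -> [N,F,H',W'].
        """
        x = self.data
        W = weight.data
        N, C, H, Wd = x.shape
        F, _, kh, kw = W.shape
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        Ho, Wo = H + 2 * pad - kh + 1, Wd + 2 * pad - kw + 1
        cols = _im2col(xp, kh, kw, Ho, Wo)            # [N, C*kh*kw, Ho*Wo]
        Wm = W.reshape(F, -1)                         # [F, C*kh*kw]
        out = np.einsum("fk,nkp->nfp", Wm, cols).reshape(N, F, Ho, Wo)
        out += bias.data.reshape(1, F, 1, 1)

        def bwd(g):
            gm = g.reshape(N, F, -1)                  # [N, F, P]
            bias._accum(g.sum(axis=(0, 2, 3)))
            gW = np.einsum("nfp,nkp->fk", gm, cols).reshape(W.shape)
            weight._accum(gW)
            if self.requires_grad:
                gcols = np.einsum("fk,nfp->nkp", Wm, gm)
                gx = _col2im(gcols, xp.shape, kh, kw, Ho, Wo)
                self._accum(gx[:, :, pad:pad + H, pad:pad + Wd])

        return self._make(out, (self, weight, bias), bwd)

    def maxpool2(self):
        """2x2 max pooling, stride 2 (input H, W must be even)."""
        N, C, H, W = self.data.shape
        x = self.data.reshape(N, C, H // 2, 2, W // 2, 2)
        xf = x.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
        idx = xf.argmax(axis=-1)
        out = np.take_along_axis(xf, idx[..., None], axis=-1)[..., 0]

        def bwd(g):
            gx = np.zeros_like(xf)
            np.put_along_axis(gx, idx[..., None], g[..., None], axis=-1)
            gx = gx.reshape(N, C, H // 2, W // 2, 2, 2) \
                   .transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W)
            self._accum(gx)

        return self._make(out, (self,), bwd)

    def global_avg_pool(self):
        """[N, C, H, W] -> [N, C]."""
        N, C, H, W = self.data.shape

        def bwd(g):
            self._accum(np.broadcast_to(
                g[:, :, None, None] / (H * W), self.data.shape).copy())

        return self._make(self.data.mean(axis=(2, 3)), (self,), bwd)

    def upsample2(self):
        """Nearest-neighbour 2x upsampling of [N, C, H, W]."""
        def bwd(g):
            N, C, H2, W2 = g.shape
            self._accum(g.reshape(N, C, H2 // 2, 2, W2 // 2, 2)
                         .sum(axis=(3, 5)))

        return self._make(self.data.repeat(2, axis=2).repeat(2, axis=3),
                          (self,), bwd)


def concat_channels(tensors):
    """Concatenate [N, C_i, H, W] tensors along the channel axis."""
    datas = [t.data for t in tensors]
    sizes = [d.shape[1] for d in datas]
    out_data = np.concatenate(datas, axis=1)
    out = Tensor(out_data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)

        def bwd(g):
            ofs = 0
            for t, c in zip(tensors, sizes):
                t._accum(g[:, ofs:ofs + c])
                ofs += c

        out._backward = bwd
    return out


def _im2col(xp, kh, kw, Ho, Wo):
    N, C = xp.shape[:2]
    s = xp.strides
    shape = (N, C, kh, kw, Ho, Wo)
    strides = (s[0], s[1], s[2], s[3], s[2], s[3])
    patches = np.lib.stride_tricks.as_strided(xp, shape, strides)
    return patches.reshape(N, C * kh * kw, Ho * Wo)


def _col2im(gcols, xp_shape, kh, kw, Ho, Wo):
    N, C = xp_shape[:2]
    gx = np.zeros(xp_shape)
    g6 = gcols.reshape(N, C, kh, kw, Ho, Wo)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i:i + Ho, j:j + Wo] += g6[:, :, i, j]
    return gx


def _unbroadcast(g, shape):
    """Reduce gradient g to the original (possibly broadcast) shape."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)
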