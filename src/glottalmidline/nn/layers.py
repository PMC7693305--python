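"""Parameterised layers on top of the autodiff tensors."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat_channels

__all__ = ["Layer", "Conv2D", "Dense", "ConvLSTM2D", "count_parameters"]


class Layer:
    """Base: a container of named parameter tensors."""

    def parameters(self) -> list[Tensor]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Layer):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Layer):
                        out.extend(item.parameters())
        return out


class Conv2D(Layer):
    """kxk cross-correlation, He-initialised, same padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel * kernel
        self.weight = Tensor(rng.normal(0, np.sqrt(2.0 / fan_in),
                                        (c_out, c_in, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.pad = kernel // 2

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, pad=self.pad)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(rng.normal(0, np.sqrt(2.0 / n_in), (n_in, n_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class ConvLSTM2D(Layer):
    """Convolutional LSTM cell over [T, N, C, H, W] sequences.

    Gates are convolutions of the input and the hidden state
    (input/forget/output gates sigmoid, candidate tanh); the spatial
    resolution is preserved.
    """

    def __init__(self, c_in: int, filters: int, kernel: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.filters = filters
        self.wx = Conv2D(c_in, 4 * filters, kernel, rng)
        self.wh = Conv2D(filters, 4 * filters, kernel, rng)
        # forget-gate bias starts at 1 (standard LSTM initialisation)
        b = np.zeros(4 * filters)
        b[filters:2 * filters] = 1.0
        self.wx.bias = Tensor(b, requires_grad=True)

    def __call__(self, xs: list[Tensor]) -> Tensor:
        """Run over the sequence; returns the final hidden state."""
        n, _, H, W = xs[0].data.shape
        f = self.filters
        h = Tensor(np.zeros((n, f, H, W)))
        c = Tensor(np.zeros((n, f, H, W)))
        for x in xs:
            z = self.wx(x) + self.wh(h)
            zi = _slice_channels(z, 0, f).sigmoid()
            zf = _slice_channels(z, f, 2 * f).sigmoid()
            zo = _slice_channels(z, 2 * f, 3 * f).sigmoid()
            zg = _slice_channels(z, 3 * f, 4 * f).tanh()
            c = zf * c + zi * zg
            h = zo * c.tanh()
        return h


def _slice_channels(t: Tensor, a: int, b: int) -> Tensor:
    out = Tensor(t.data[:, a:b])
    out.requires_grad = t.requires_grad
    if out.requires_grad:
        out._parents = (t,)

        def bwd(g):
            full = np.zeros_like(t.data)
            full[:, a:b] = g
            t._accum(full)

        out._backward = bwd
    return out


def count_parameters(layer: Layer) -> int:
    return sum(p.data.size for p in layer.parameters())
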