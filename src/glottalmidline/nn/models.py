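"""Network architectures for glottal midline keypoint prediction.

* ``MidlineNet`` — a lean convolutional regressor derived from the
  U-Net encoder: four blocks of two 3x3 convolutions (32 filters) and a
  2x2 max pool, ReLU throughout, global average pooling and a dense
  head emitting the four values (x, y of the posterior and anterior
  point, normalised to [0, 1] image fractions).
* ``RecurrentMidlineNet`` — the same topology with the convolutions of
  each block replaced by a ConvLSTM2D layer: single frames of a window
  are fed step by step and the regression reads the final hidden state
  (spatial pooling per block is applied to the per-step outputs).
* ``GlottisNet`` — a multi-task encoder-decoder: a U-Net-style
  segmentation path with skip connections plus a keypoint head that
  reads the latent space (bottleneck) through global average pooling.

Specs are plain dataclasses so architecture contracts (output shapes,
parameter counts) can be tested at full size without training; builders
accept reduced widths/depths for smoke-scale training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat_channels
from .layers import Layer, Conv2D, Dense, ConvLSTM2D, count_parameters

__all__ = [
    "MidlineNetSpec",
    "RecurrentSpec",
    "GlottisNetSpec",
    "MidlineNet",
    "RecurrentMidlineNet",
    "GlottisNet",
    "build",
]


@dataclass
class MidlineNetSpec:
    blocks: int = 4
    convs_per_block: int = 2
    filters: int = 32
    kernel: int = 3
    in_channels: int = 1
    out_dim: int = 4

    def parameter_count(self) -> int:
        """Closed-form count (convolutions + dense head)."""
        n, c_in = 0, self.in_channels
        for _ in range(self.blocks):
            for _ in range(self.convs_per_block):
                n += self.filters * (c_in * self.kernel ** 2 + 1)
                c_in = self.filters
        n += (self.filters + 1) * self.out_dim
        return n


@dataclass
class RecurrentSpec:
    blocks: int = 4
    filters: int = 128            # best range reported: 128-256
    kernel: int = 3
    in_channels: int = 1
    out_dim: int = 4
    seq_len: int = 15             # best range reported: 15-21

    def __post_init__(self) -> None:
        if not 1 <= self.seq_len:
            raise ValueError("seq_len must be positive")


@dataclass
class GlottisNetSpec:
    depth: int = 4
    base_filters: int = 32
    kernel: int = 3
    in_channels: int = 1
    out_dim: int = 4


class MidlineNet(Layer):
    def __init__(self, spec: MidlineNetSpec | None = None, seed: int = 0):
        self.spec = spec or MidlineNetSpec()
        rng = np.random.default_rng(seed)
        self.convs = []
        c = self.spec.in_channels
        for _ in range(self.spec.blocks):
            block = []
            for _ in range(self.spec.convs_per_block):
                block.append(Conv2D(c, self.spec.filters, self.spec.kernel,
                                    rng))
                c = self.spec.filters
            self.convs.append(block)
        self.head = Dense(self.spec.filters, self.spec.out_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        """x [N, C, H, W] -> keypoints [N, 4] (x_P, y_P, x_A, y_A)."""
        for block in self.convs:
            for conv in block:
                x = conv(x).relu()
            x = x.maxpool2()
        return self.head(x.global_avg_pool())

    def parameters(self):
        out = []
        for block in self.convs:
            for conv in block:
                out.extend(conv.parameters())
        out.extend(self.head.parameters())
        return out


class RecurrentMidlineNet(Layer):
    """MidlineNet with ConvLSTM2D blocks over frame sequences."""

    def __init__(self, spec: RecurrentSpec | None = None, seed: int = 0):
        self.spec = spec or RecurrentSpec()
        rng = np.random.default_rng(seed)
        self.cells = []
        c = self.spec.in_channels
        for _ in range(self.spec.blocks):
            self.cells.append(ConvLSTM2D(c, self.spec.filters,
                                         self.spec.kernel, rng))
            c = self.spec.filters
        self.head = Dense(self.spec.filters, self.spec.out_dim, rng)

    def __call__(self, frames: list[Tensor]) -> Tensor:
        """frames: list of [N, C, H, W] tensors (time steps).

        Each block's per-step hidden states are spatially pooled and
        passed to the next block as a sequence; the regression reads
        the final step of the last block.
        """
        xs = frames
        final = None
        for k, cell in enumerate(self.cells):
            steps = _per_step(cell, xs)
            if k < len(self.cells) - 1:
                xs = [h.maxpool2() for h in steps]
            else:
                final = steps[-1]
        return self.head(final.global_avg_pool())

    def parameters(self):
        out = []
        for cell in self.cells:
            out.extend(cell.parameters())
        out.extend(self.head.parameters())
        return out


def _per_step(cell: ConvLSTM2D, xs: list[Tensor]) -> list[Tensor]:
    """Hidden states of every time step (recomputed rollout)."""
    n, _, H, W = xs[0].data.shape
    f = cell.filters
    h = Tensor(np.zeros((n, f, H, W)))
    c = Tensor(np.zeros((n, f, H, W)))
    outs = []
    from .layers import _slice_channels
    for x in xs:
        z = cell.wx(x) + cell.wh(h)
        zi = _slice_channels(z, 0, f).sigmoid()
        zf = _slice_channels(z, f, 2 * f).sigmoid()
        zo = _slice_channels(z, 2 * f, 3 * f).sigmoid()
        zg = _slice_channels(z, 3 * f, 4 * f).tanh()
        c = zf * c + zi * zg
        h = zo * c.tanh()
        outs.append(h)
    return outs


class GlottisNet(Layer):
    """Multi-task encoder-decoder with a latent-space keypoint head."""

    def __init__(self, spec: GlottisNetSpec | None = None, seed: int = 0):
        self.spec = spec or GlottisNetSpec()
        rng = np.random.default_rng(seed)
        s = self.spec
        self.enc = []
        c = s.in_channels
        f = s.base_filters
        for _ in range(s.depth):
            self.enc.append([Conv2D(c, f, s.kernel, rng),
                             Conv2D(f, f, s.kernel, rng)])
            c, f = f, f * 2
        self.bottleneck = [Conv2D(c, f, s.kernel, rng),
                           Conv2D(f, f, s.kernel, rng)]
        self.dec = []
        for _ in range(s.depth):
            f //= 2
            # after upsample (2f ch) + skip (f ch) -> f
            self.dec.append([Conv2D(f * 2 + f, f, s.kernel, rng),
                             Conv2D(f, f, s.kernel, rng)])
        self.seg_out = Conv2D(f, 1, 1, rng)
        self.kp_head = Dense(s.base_filters * 2 ** s.depth, s.out_dim, rng)

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (segmentation map [N,1,H,W] in (0,1), keypoints [N,4])."""
        skips = []
        for c1, c2 in self.enc:
            x = c2(c1(x).relu()).relu()
            skips.append(x)
            x = x.maxpool2()
        x = self.bottleneck[1](self.bottleneck[0](x).relu()).relu()
        latent = x
        for (c1, c2), skip in zip(self.dec, reversed(skips)):
            x = concat_channels([x.upsample2(), skip])
            x = c2(c1(x).relu()).relu()
        seg = self.seg_out(x).sigmoid()
        kp = self.kp_head(latent.global_avg_pool())
        return seg, kp

    def parameters(self):
        out = []
        for c1, c2 in self.enc + [tuple(self.bottleneck)] + self.dec:
            out.extend(c1.parameters())
            out.extend(c2.parameters())
        out.extend(self.seg_out.parameters())
        out.extend(self.kp_head.parameters())
        return out


def build(spec) -> Layer:
    """Instantiate the model matching a spec dataclass."""
    if isinstance(spec, MidlineNetSpec):
        return MidlineNet(spec)
    if isinstance(spec, RecurrentSpec):
        return RecurrentMidlineNet(spec)
    if isinstance(spec, GlottisNetSpec):
        return GlottisNet(spec)
    raise TypeError(f"unknown spec type: {type(spec).__name__}")
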