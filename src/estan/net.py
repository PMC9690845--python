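"""The dual-encoder segmentation network and its single-encoder ablation.

The model pairs a conventional contracting path (five blocks of two 3x3
convolutions plus 2x2 max pooling, the fifth block unpooled) with a second
encoder whose blocks run two branches in parallel: a stack of two small
square kernels, and a row-column branch applying an A3x1 then a 1xA3
convolution (A3 shrinking 15, 13, 11, 9, 7 with depth) closed by a square
kernel. The branches are summed element-wise and fused by an A5 kernel
(5x5 in blocks 2 and 5, 1x1 elsewhere), adding one extra non-linearity per
block. The cross-shaped receptive footprint of the row-column pair aligns
with the horizontally layered anatomy of breast ultrasound images.

The decoder has four up blocks. Each upsamples 2x, concatenates the
matching-resolution first-convolution output of the basic encoder and the
fused output of the second encoder (first skip), applies a 3x3 convolution,
an M2 channel-control convolution (1x1 in blocks 1-3, 5x5 in block 4),
concatenates the basic encoder's second-convolution output (second skip),
and closes with a 3x3 convolution. A 1x1 convolution plus sigmoid yields a
per-pixel tumor probability. All convolutions are zero-padded "same", so
the output shape equals the input shape for any side divisible by 16.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .config import NetConfig


class Conv:
    """A same-padded convolution layer with He-uniform initialized weights."""

    def __init__(self, kh, kw, cin, cout, rng, name=""):
        fan_in = kh * kw * cin
        bound = np.sqrt(6.0 / fan_in)
        self.w = ad.parameter(rng.uniform(-bound, bound, size=(kh, kw, cin, cout)),
                              name=f"{name}.w")
        self.b = ad.parameter(np.zeros(cout), name=f"{name}.b")
        self.name = name

    def __call__(self, x: Tensor) -> Tensor:
        return ad.relu(ad.conv2d(x, self.w, self.b))

    def linear(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.w, self.b)

    @property
    def params(self):
        return [self.w, self.b]

    def n_params(self) -> int:
        return int(self.w.data.size + self.b.data.size)


class UpSample:
    """2x upsampling: transposed 2x2 stride-2 convolution, or nearest + 1x1."""

    def __init__(self, cin, cout, rng, mode="transposed", name=""):
        self.mode = mode
        if mode == "transposed":
            bound = np.sqrt(6.0 / (2 * 2 * cin))
            self.w = ad.parameter(rng.uniform(-bound, bound, size=(2, 2, cin, cout)),
                                  name=f"{name}.w")
        else:
            bound = np.sqrt(6.0 / cin)
            self.w = ad.parameter(rng.uniform(-bound, bound, size=(1, 1, cin, cout)),
                                  name=f"{name}.w")
        self.b = ad.parameter(np.zeros(cout), name=f"{name}.b")
        self.name = name

    def __call__(self, x: Tensor) -> Tensor:
        if self.mode == "transposed":
            return ad.relu(ad.conv_transpose2x(x, self.w, self.b))
        up = Tensor(np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2), parents=(x,))
        n, h, w, c = x.shape

        def backward_fn(gy):
            g = gy.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4))
            x._accumulate(g)

        up.backward_fn = backward_fn
        return ad.relu(ad.conv2d(up, self.w, self.b))

    @property
    def params(self):
        return [self.w, self.b]

    def n_params(self) -> int:
        return int(self.w.data.size + self.b.data.size)


@dataclass
class BlockTaps:
    """Skip-connection sources captured from one encoder block."""
    tap1: Tensor          # basic: first conv; dual encoder: fused A5 output
    tap2: Tensor | None   # basic encoder only: second conv output
    out: Tensor           # post-pooling block output (block 5: unpooled)


class BasicBlock:
    """Two 3x3 ReLU convolutions; 2x2 max pool except in the last block."""

    def __init__(self, j, cin, cfg: NetConfig, rng):
        k, c = cfg.basic_kernel, cfg.channels[j]
        self.j = j
        self.pool = j < 4
        self.conv1 = Conv(k, k, cin, c, rng, name=f"basic{j + 1}.conv1")
        self.conv2 = Conv(k, k, c, c, rng, name=f"basic{j + 1}.conv2")

    def __call__(self, x: Tensor) -> BlockTaps:
        t1 = self.conv1(x)
        t2 = self.conv2(t1)
        out = ad.maxpool2x2(t2) if self.pool else t2
        return BlockTaps(tap1=t1, tap2=t2, out=out)

    @property
    def layers(self):
        return [self.conv1, self.conv2]


class EstanBlock:
    """Dual-branch block: square stack + row-column branch, summed and fused."""

    def __init__(self, j, cin, cfg: NetConfig, rng):
        c = cfg.channels[j]
        a1, a2, a4 = cfg.estan_square_sizes
        a3 = cfg.estan_rowcol_sizes[j]
        a5 = cfg.estan_a5_sizes[j]
        n = f"estan{j + 1}"
        self.j = j
        self.pool = j < 4
        self.sq1 = Conv(a1, a1, cin, c, rng, name=f"{n}.sq1")
        self.sq2 = Conv(a2, a2, c, c, rng, name=f"{n}.sq2")
        self.col = Conv(a3, 1, cin, c, rng, name=f"{n}.col")   # A3 x 1
        self.row = Conv(1, a3, c, c, rng, name=f"{n}.row")     # 1 x A3
        self.sq4 = Conv(a4, a4, c, c, rng, name=f"{n}.sq4")
        self.fuse = Conv(a5, a5, c, c, rng, name=f"{n}.fuse")

    def __call__(self, x: Tensor) -> BlockTaps:
        branch1 = self.sq2(self.sq1(x))
        branch2 = self.sq4(self.row(self.col(x)))
        fused = self.fuse(ad.add(branch1, branch2))
        out = ad.maxpool2x2(fused) if self.pool else fused
        return BlockTaps(tap1=fused, tap2=None, out=out)

    @property
    def layers(self):
        return [self.sq1, self.sq2, self.col, self.row, self.sq4, self.fuse]


class UpBlock:
    """Upsample, fuse the two encoders' skips, and refine (three convolutions)."""

    def __init__(self, j, cin, skip1_ch, skip2_ch, cfg: NetConfig, rng):
        y = cfg.decoder_channels[j]
        m2 = cfg.decoder_m2[j]
        n = f"up{j + 1}"
        self.j = j
        self.up = UpSample(cin, y, rng, mode=cfg.upsample_mode, name=f"{n}.up")
        self.conv1 = Conv(cfg.decoder_m1, cfg.decoder_m1, y + skip1_ch, y, rng,
                          name=f"{n}.conv1")
        self.conv2 = Conv(m2, m2, y, y, rng, name=f"{n}.conv2")
        self.conv3 = Conv(cfg.decoder_m3, cfg.decoder_m3, y + skip2_ch, y, rng,
                          name=f"{n}.conv3")

    def __call__(self, x: Tensor, taps_basic: BlockTaps,
                 taps_estan: BlockTaps | None) -> Tensor:
        u = self.up(x)
        for t in (taps_basic.tap1,) + ((taps_estan.tap1,) if taps_estan else ()):
            if t.shape[1:3] != u.shape[1:3]:
                raise ValueError(
                    f"up block {self.j + 1}: skip resolution {t.shape[1:3]} does "
                    f"not match upsampled {u.shape[1:3]}")
        skips = [u, taps_basic.tap1] + ([taps_estan.tap1] if taps_estan else [])
        a = self.conv1(ad.concat(skips))
        b = self.conv2(a)
        c = self.conv3(ad.concat([b, taps_basic.tap2]))
        return c

    @property
    def layers(self):
        return [self.up, self.conv1, self.conv2, self.conv3]


class Model:
    """End-to-end segmentation network: image (N,H,W,1) -> probability map."""

    def __init__(self, config: NetConfig, seed: int = 0, variant: str = "estan"):
        if variant not in ("estan", "basic"):
            raise ValueError(f"unknown variant {variant!r}")
        cfg = config.validate()
        self.config = cfg
        self.variant = variant
        rng = np.random.default_rng(seed)
        ch = cfg.channels
        ins = [cfg.in_channels] + ch[:-1]
        self.basic_blocks = [BasicBlock(j, ins[j], cfg, rng) for j in range(5)]
        self.estan_blocks = ([EstanBlock(j, ins[j], cfg, rng) for j in range(5)]
                             if variant == "estan" else [])
        bottleneck_ch = ch[-1] * (2 if variant == "estan" else 1)
        self.up_blocks = []
        cin = bottleneck_ch
        for j in range(4):
            level = 3 - j                      # encoder level feeding up block j
            skip1 = ch[level] * (2 if variant == "estan" else 1)
            skip2 = ch[level]
            blk = UpBlock(j, cin, skip1, skip2, cfg, rng)
            self.up_blocks.append(blk)
            cin = cfg.decoder_channels[j]
        self.head = Conv(1, 1, cin, 1, rng, name="head")

    # -- forward -----------------------------------------------------------

    def forward(self, images: np.ndarray) -> Tensor:
        """Run the network; images is (N, H, W) or (N, H, W, 1) in [0, 1]."""
        x = np.asarray(images, dtype=ad.DTYPE)
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1] % 16 or x.shape[2] % 16:
            raise ValueError(
                f"input side must be divisible by 16 (four pooling stages), "
                f"got {x.shape[1]}x{x.shape[2]}")
        t = Tensor(x)
        taps_b, taps_e = [], []
        xb = t
        for blk in self.basic_blocks:
            taps = blk(xb)
            taps_b.append(taps)
            xb = taps.out
        if self.variant == "estan":
            xe = t
            for blk in self.estan_blocks:
                taps = blk(xe)
                taps_e.append(taps)
                xe = taps.out
            bottom = ad.concat([xb, xe])
        else:
            bottom = xb
        y = bottom
        for j, blk in enumerate(self.up_blocks):
            level = 3 - j
            y = blk(y, taps_b[level], taps_e[level] if taps_e else None)
        return ad.sigmoid(self.head.linear(y))

    __call__ = forward

    def predict(self, images: np.ndarray, batch_size: int = 4) -> np.ndarray:
        """Probability maps (N, H, W) without building a backward graph."""
        x = np.asarray(images, dtype=ad.DTYPE)
        if x.ndim == 3:
            x = x[..., None]
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(self.forward(x[i:i + batch_size]).data[..., 0])
        return np.concatenate(outs, axis=0)

    # -- parameters --------------------------------------------------------

    @property
    def layer_list(self):
        layers = []
        for blk in self.basic_blocks + self.estan_blocks + self.up_blocks:
            layers.extend(blk.layers)
        layers.append(self.head)
        return layers

    @property
    def params(self):
        out = []
        for layer in self.layer_list:
            out.extend(layer.params)
        return out


def build_model(config: NetConfig | None = None, seed: int = 0,
                variant: str = "estan") -> Model:
    """Construct the network ('estan') or its single-encoder ablation ('basic')."""
    return Model(config or NetConfig(), seed=seed, variant=variant)


def count_parameters(model: Model) -> int:
    """Exact number of trainable scalars."""
    return sum(p.data.size for p in model.params)


def layer_table(model: Model) -> "pd.DataFrame":
    """One row per layer: name, kernel, in/out channels, parameter count."""
    import pandas as pd

    rows = []
    for layer in model.layer_list:
        kh, kw, cin, cout = layer.w.shape
        rows.append({"layer": layer.name, "kernel": f"{kh}x{kw}",
                     "in_ch": cin, "out_ch": cout, "params": layer.n_params()})
    return pd.DataFrame(rows)


def summarize(model: Model) -> str:
    df = layer_table(model)
    total = count_parameters(model)
    return (df.to_string(index=False)
            + f"\ntotal trainable parameters: {total:,}")
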