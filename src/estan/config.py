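"""Configuration objects for the phantom generator, the network and training.

Every schedule printed for the architecture lives here so that the model
builder is purely declarative: encoder channels per block, the basic
encoder's square kernel size, the row-column kernel lengths A3 per block,
the fusion kernel sizes A5, the decoder channel and kernel schedules.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import yaml


@dataclass
class NetConfig:
    """Complete kernel/channel schedules for both encoders and the decoder.

    Defaults reproduce the published architecture: five encoder levels with
    32..512 kernels, basic blocks of two 3x3 convolutions, dual-branch
    blocks whose row-column kernel length shrinks 15->7 with depth, and a
    four-level decoder with 256..32 kernels.
    """

    channels: list[int] = field(default_factory=lambda: [32, 64, 128, 256, 512])
    basic_kernel: int = 3
    estan_rowcol_sizes: list[int] = field(default_factory=lambda: [15, 13, 11, 9, 7])
    estan_a5_sizes: list[int] = field(default_factory=lambda: [1, 5, 1, 1, 5])
    # the two stacked square kernels of the first branch and the square
    # kernel closing the row-column branch (A1, A2, A4); sizes unpublished,
    # small squares keep the branch's receptive field compact
    estan_square_sizes: list[int] = field(default_factory=lambda: [3, 3, 3])
    decoder_channels: list[int] = field(default_factory=lambda: [256, 128, 64, 32])
    decoder_m1: int = 3
    decoder_m2: list[int] = field(default_factory=lambda: [1, 1, 1, 5])
    decoder_m3: int = 3
    in_channels: int = 1
    upsample_mode: str = "transposed"  # "transposed" | "nearest"

    @property
    def depth(self) -> int:
        return len(self.channels)

    def validate(self) -> "NetConfig":
        if len(self.channels) != 5:
            raise ValueError("encoder needs exactly 5 blocks")
        if len(self.decoder_channels) != 4 or len(self.decoder_m2) != 4:
            raise ValueError("decoder needs exactly 4 up blocks")
        if any(c <= 0 for c in self.channels + self.decoder_channels):
            raise ValueError("all channel counts must be positive")
        if any(a <= b for a, b in zip(self.estan_rowcol_sizes,
                                      self.estan_rowcol_sizes[1:])):
            raise ValueError("row-column kernel sizes must be strictly decreasing")
        if len(self.estan_square_sizes) != 3:
            raise ValueError("estan_square_sizes holds the three square kernels A1,A2,A4")
        if self.upsample_mode not in ("transposed", "nearest"):
            raise ValueError(f"unknown upsample mode {self.upsample_mode!r}")
        return self

    def scaled(self, divisor: int) -> "NetConfig":
        """Width-scaled copy (channels // divisor), for CPU-sized experiments."""
        cfg = dataclasses.replace(
            self,
            channels=[max(1, c // divisor) for c in self.channels],
            decoder_channels=[max(1, c // divisor) for c in self.decoder_channels],
        )
        return cfg.validate()


@dataclass
class PhantomConfig:
    """Geometry and texture controls for one synthetic breast-ultrasound image.

    The image is built from four horizontal tissue bands (top to bottom:
    skin, premammary fat, mammary, retromammary), a hypoechoic elliptical
    tumor seated in the mammary band, optional posterior shadowing, and a
    smoothed unit-mean multiplicative speckle field. All intensities are in
    [0, 1]; lengths are in pixels of the original (un-resized) image.
    """

    height: int = 500
    width: int = 500
    layer_fractions: tuple[float, float, float, float] = (0.08, 0.17, 0.45, 0.30)
    layer_means: tuple[float, float, float, float] = (0.75, 0.35, 0.55, 0.25)
    speckle_shape: float = 4.0      # gamma concentration; math.inf disables speckle
    speckle_smoothing_sigma: float = 1.5
    tumor_axis_px: float = 120.0    # requested longest-axis length
    tumor_aspect: float = 0.6       # minor/major axis ratio, (0, 1]
    tumor_angle: float = 0.0        # radians, 0 = major axis horizontal
    boundary_irregularity: float = 0.15   # relative radial perturbation, [0, 0.5]
    tumor_contrast: float = 0.35    # intensity drop inside the tumor
    shadow_strength: float = 0.0    # posterior attenuation, [0, 1]; off by default
    tumor_center: tuple[float, float] | None = None  # (row, col); default random in mammary band
    seed: int = 0

    def validate(self) -> "PhantomConfig":
        if self.height < 8 or self.width < 8:
            raise ValueError("image must be at least 8x8")
        if len(self.layer_fractions) != 4:
            raise ValueError("exactly four tissue layers required")
        if any(f <= 0 for f in self.layer_fractions):
            raise ValueError(f"all layer fractions must be > 0, got {self.layer_fractions}")
        if abs(sum(self.layer_fractions) - 1.0) > 1e-9:
            raise ValueError(f"layer fractions must sum to 1, got {sum(self.layer_fractions)}")
        if not all(0.0 <= m <= 1.0 for m in self.layer_means):
            raise ValueError("layer means must lie in [0, 1]")
        if not (self.speckle_shape > 0):
            raise ValueError("speckle_shape must be positive (use math.inf to disable)")
        if self.tumor_axis_px <= 0:
            raise ValueError("tumor_axis_px must be positive")
        if not (0 < self.tumor_aspect <= 1):
            raise ValueError("tumor_aspect must be in (0, 1]")
        if not (0.0 <= self.boundary_irregularity <= 0.5):
            raise ValueError("boundary_irregularity must be in [0, 0.5]")
        if not (0.0 <= self.tumor_contrast <= 1.0):
            raise ValueError("tumor_contrast must be in [0, 1]")
        if not (0.0 <= self.shadow_strength <= 1.0):
            raise ValueError("shadow_strength must be in [0, 1]")
        return self

    @property
    def speckle_enabled(self) -> bool:
        return math.isfinite(self.speckle_shape)


@dataclass
class TrainConfig:
    """Training-loop hyperparameters (the source work publishes none)."""

    epochs: int = 100
    batch_size: int = 8
    lr: float = 1e-4
    optimizer: str = "adam"        # "adam" | "sgd"
    seed: int = 0
    loss: str = "dice"
    dice_eps: float = 1.0
    augment_flip: bool = False
    augment_shift: bool = False
    device: str = "cpu"
    # optional convergence gate: stop once training DSC exceeds this value,
    # checked every `eval_every` epochs (None = always run all epochs)
    early_stop_dsc: float | None = None
    eval_every: int = 10

    def validate(self) -> "TrainConfig":
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr < 0:
            raise ValueError("learning rate must be >= 0")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.loss != "dice":
            raise ValueError("only the Dice loss is supported")
        return self


def _from_mapping(cls, mapping):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(mapping)
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list) and "tuple" in str(f.type):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs).validate()


def load_yaml_config(path):
    """Load a YAML file with optional top-level net/phantom/train sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    if "net" in raw:
        out["net"] = _from_mapping(NetConfig, raw["net"])
    if "phantom" in raw:
        out["phantom"] = _from_mapping(PhantomConfig, raw["phantom"])
    if "train" in raw:
        out["train"] = _from_mapping(TrainConfig, raw["train"])
    return out
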