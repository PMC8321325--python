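"""Configuration dataclasses and YAML loading.

``NetConfig`` captures the width/depth/input-size knobs of the network; its
defaults instantiate the published architecture (448 px input, ResNet-style
channel widths, 23 dilated Conv4 blocks).  ``width_mult`` scales every channel
count uniformly, which lets the same code run as a CPU-sized model
(e.g. 64 px input with ``width_mult=1/8``) for tests and experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import yaml


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


@dataclass(frozen=True)
class NetConfig:
    input_size: int = 448
    width_mult: float = 1.0
    conv4_blocks: int = 23
    ppm_bins: tuple = (1, 2, 3, 6)
    ppm_out_channels: int = 128
    decoder_bottleneck: int = 32  # 3x3 bottleneck width inside decoder blocks

    def __post_init__(self):
        if self.input_size % 8 != 0:
            raise ConfigError(
                f"input_size must be divisible by 8 (three 2x reductions), got {self.input_size}"
            )
        if self.width_mult <= 0:
            raise ConfigError("width_mult must be positive")
        if self.conv4_blocks < 1:
            raise ConfigError("conv4_blocks must be >= 1")
        if self.scaled(self.ppm_out_channels) % 4 != 0 and self.scaled(self.ppm_out_channels) < 4:
            raise ConfigError("scaled ppm_out_channels must allow 4 pyramid branches")

    def scaled(self, base: int) -> int:
        """Channel count after width scaling; never below 1."""
        return max(1, round(base * self.width_mult))

    # stage widths of the truncated residual encoder (Conv1..Conv4)
    @property
    def c1(self):
        return self.scaled(64)

    @property
    def c2(self):
        return self.scaled(256)

    @property
    def c3(self):
        return self.scaled(512)

    @property
    def c4(self):
        return self.scaled(1024)

    @property
    def feature_channels(self):
        """Channels of the shared feature map F (PPM output)."""
        return self.scaled(self.ppm_out_channels)

    @property
    def feature_size(self):
        return self.input_size // 8


ABLATION_MODES = ("seg_only", "seg_edge", "full")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    epochs: int = 30
    lr: float = 1e-4
    lr_gamma: float = 0.9  # per-epoch exponential decay
    alpha: float = 0.05    # task balance: L = alpha * L_seg + L_edge
    mode: str = "full"
    seed: int = 0
    val_fraction: float = 0.15
    augment: bool = True

    def __post_init__(self):
        if self.mode not in ABLATION_MODES:
            raise ConfigError(f"mode must be one of {ABLATION_MODES}, got {self.mode!r}")
        for name in ("batch_size", "epochs", "lr", "lr_gamma", "alpha"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


@dataclass(frozen=True)
class AugmentConfig:
    """Train-time augmentation toggles; defaults mirror the training protocol."""

    hflip: bool = True
    vflip: bool = True
    crop_scale: tuple = (0.75, 1.25)
    rotate_degrees: float = 20.0
    gt_crop_pad: int = 50
    mls_warp: bool = True
    mls_grid: int = 4
    mls_max_shift: float = 0.05  # fraction of image side
    edge_thickness: int = 2


def _build(dc_type, mapping):
    if mapping is None:
        return dc_type()
    names = {f.name for f in fields(dc_type)}
    unknown = set(mapping) - names
    if unknown:
        raise ConfigError(f"unknown {dc_type.__name__} keys: {sorted(unknown)}")
    kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in mapping.items()}
    return dc_type(**kwargs)


def load_config(path):
    """Read a YAML config with ``model:``, ``train:``, ``augment:``, ``loss:``
    and ``predict:`` sections into config objects; missing sections use defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    train_map = dict(raw.get("train") or {})
    if "alpha" in (raw.get("loss") or {}):
        train_map["alpha"] = raw["loss"]["alpha"]
    return {
        "model": _build(NetConfig, raw.get("model")),
        "train": _build(TrainConfig, train_map),
        "augment": _build(AugmentConfig, raw.get("augment")),
        "predict": dict(raw.get("predict") or {"tta": True}),
    }


def shrink_for_tests(cfg: NetConfig | None = None) -> NetConfig:
    """The CPU-sized configuration used throughout the test suite."""
    base = cfg or NetConfig()
    return replace(base, input_size=64, width_mult=1 / 8, conv4_blocks=2)
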