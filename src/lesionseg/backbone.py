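"""Shared encoder: truncated dilated residual network plus pyramid pooling.

The encoder follows the classic bottleneck residual design, cut after its
fourth stage.  The three 2x spatial reductions (stride-2 stem conv, stem max
pool, stride-2 entry to stage 3) take a ``S``-pixel input to ``S/8``; the
fourth stage keeps that resolution by using stride 1 with dilation 2 in its
3x3 convolutions.  A pyramid pooling module (PPM) then pools the stage-4 map
at several bin sizes, reduces each pooled map with a 1x1 conv, upsamples,
concatenates with the stage-4 map and fuses everything into the shared
feature map ``F``.

At default configuration (448 px input, width 1) the stage shapes are::

    Conv1 (64, 224, 224)   Conv2 (256, 112, 112)   Conv3 (512, 56, 56)
    Conv4 (1024, 56, 56)   F     (128, 56, 56)
"""

from __future__ import annotations

from . import nn
from .config import NetConfig


class Bottleneck(nn.Module):
    """1x1 reduce -> 3x3 (stride/dilation) -> 1x1 expand, with projection skip."""

    def __init__(self, in_ch, mid_ch, out_ch, stride=1, dilation=1):
        super().__init__()
        self.reduce = nn.conv_bn_relu(in_ch, mid_ch, 1)
        self.conv = nn.conv_bn_relu(mid_ch, mid_ch, 3, stride=stride,
                                    padding=dilation, dilation=dilation)
        self.expand = nn.Sequential(
            nn.Conv2d(mid_ch, out_ch, 1, bias=False),
            nn.BatchNorm2d(out_ch),
        )
        if in_ch != out_ch or stride != 1:
            self.project = nn.Sequential(
                nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False),
                nn.BatchNorm2d(out_ch),
            )
        else:
            self.project = None

    def forward(self, x):
        identity = self.project(x) if self.project is not None else x
        h = self.expand(self.conv(self.reduce(x)))
        return nn.relu(h + identity)


def _stage(in_ch, mid_ch, out_ch, blocks, stride=1, dilation=1):
    layers = [Bottleneck(in_ch, mid_ch, out_ch, stride=stride, dilation=dilation)]
    layers += [Bottleneck(out_ch, mid_ch, out_ch, dilation=dilation)
               for _ in range(blocks - 1)]
    return nn.Sequential(*layers)


class PyramidPooling(nn.Module):
    """Multi-bin context pooling fused back into the input map."""

    def __init__(self, in_ch, out_ch, bins=(1, 2, 3, 6)):
        super().__init__()
        self.bins = tuple(bins)
        branch_ch = max(1, out_ch // len(self.bins))
        self.branches = nn.ModuleList(
            nn.conv_bn_relu(in_ch, branch_ch, 1) for _ in self.bins
        )
        self.fuse = nn.conv_bn_relu(in_ch + branch_ch * len(self.bins), out_ch, 3, padding=1)

    def forward(self, x):
        h, w = x.data.shape[2], x.data.shape[3]
        feats = [x]
        for b, branch in zip(self.bins, self.branches):
            pooled = nn.adaptive_avg_pool2d(x, b)
            feats.append(nn.resize_bilinear(branch(pooled), h, w))
        return self.fuse(nn.concat(feats, axis=1))


class Backbone(nn.Module):
    """Encoder producing the shared feature map F."""

    def __init__(self, cfg: NetConfig, dilate_conv4: bool = True):
        super().__init__()
        self.cfg = cfg
        c1, c2, c3, c4 = cfg.c1, cfg.c2, cfg.c3, cfg.c4
        self.stem = nn.conv_bn_relu(3, c1, 7, stride=2, padding=3)
        self.pool = nn.MaxPool2d(3, stride=2, padding=1)
        self.stage2 = _stage(c1, cfg.scaled(64), c2, blocks=3)
        self.stage3 = _stage(c2, cfg.scaled(128), c3, blocks=4, stride=2)
        if dilate_conv4:
            self.stage4 = _stage(c3, cfg.scaled(256), c4, blocks=cfg.conv4_blocks,
                                 stride=1, dilation=2)
        else:
            # negative-control wiring: ordinary stride-2 stage, halves resolution
            self.stage4 = _stage(c3, cfg.scaled(256), c4, blocks=cfg.conv4_blocks,
                                 stride=2, dilation=1)
        self.ppm = PyramidPooling(c4, cfg.feature_channels, bins=cfg.ppm_bins)

    def forward_stages(self, x) -> dict:
        """Forward pass returning every named stage (for shape audits)."""
        x = nn.autograd.as_tensor(x) if not isinstance(x, nn.Tensor) else x
        size = self.cfg.input_size
        if x.data.shape[2] != size or x.data.shape[3] != size:
            raise ValueError(
                f"expected {size}x{size} input, got "
                f"{x.data.shape[2]}x{x.data.shape[3]}"
            )
        out = {}
        out["conv1"] = self.stem(x)
        pooled = self.pool(out["conv1"])
        out["conv2"] = self.stage2(pooled)
        out["conv3"] = self.stage3(out["conv2"])
        out["conv4"] = self.stage4(out["conv3"])
        out["F"] = self.ppm(out["conv4"])
        return out

    def forward(self, x):
        return self.forward_stages(x)["F"]


def build_backbone(cfg: NetConfig, dilate_conv4: bool = True) -> Backbone:
    return Backbone(cfg, dilate_conv4=dilate_conv4)
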