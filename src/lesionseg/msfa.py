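"""Multi-scale feature aggregation (MSFA) prediction head.

Each of the three pyramid scales gets a small prediction head (3x3 conv at
full width + BN + ReLU, then 3x3 conv to one channel).  A fourth
single-channel map comes from a direct 1x1 convolution of the finest pyramid
level.  All four logit maps are bilinearly upsampled to the input resolution,
concatenated to a (4,S,S) stack, and linearly combined by a learned 1x1
convolution; a single sigmoid at the very end maps the aggregated logit to a
probability.  One head object serves both the mask branch and the edge
branch — the parameters are shared, which pushes the two predictions toward
similar quality.
"""

from __future__ import annotations

from . import nn
from .config import NetConfig


class ScaleHead(nn.Module):
    """Per-scale predictor: 3x3 conv (full width) + BN + ReLU, 3x3 conv to 1."""

    def __init__(self, channels: int):
        super().__init__()
        self.block = nn.conv_bn_relu(channels, channels, 3, padding=1)
        self.predict = nn.Conv2d(channels, 1, 3, padding=1)

    def forward(self, x):
        return self.predict(self.block(x))


class MSFAHead(nn.Module):
    def __init__(self, cfg: NetConfig):
        super().__init__()
        ch = cfg.feature_channels
        self.out_size = cfg.input_size
        self.heads = nn.ModuleList(ScaleHead(ch) for _ in range(3))
        self.direct = nn.Conv2d(ch, 1, 1)   # 4th map: 1x1 conv of finest level
        self.aggregate = nn.Conv2d(4, 1, 1)  # learned per-scale weighting

    def forward_stack(self, pyramid):
        """The pre-aggregation logit stack of shape (N, 4, S, S)."""
        s = self.out_size
        maps = [nn.resize_bilinear(head(level), s, s)
                for head, level in zip(self.heads, pyramid)]
        maps.append(nn.resize_bilinear(self.direct(pyramid[-1]), s, s))
        return nn.concat(maps, axis=1)

    def forward(self, pyramid):
        return nn.sigmoid(self.aggregate(self.forward_stack(pyramid)))


class DirectHead(nn.Module):
    """Ablation head: 1x1 conv + sigmoid on the finest pyramid level only
    (used when the MSFA module is removed)."""

    def __init__(self, cfg: NetConfig):
        super().__init__()
        self.predict = nn.Conv2d(cfg.feature_channels, 1, 1)

    def forward(self, pyramid):
        return nn.sigmoid(self.predict(pyramid[-1]))
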