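"""Dual task decoders (Seg subnet, Edge subnet) with cross-connections.

Each branch is a chain of three residual up-blocks.  A block keeps its channel
count (1x1 -> full width, 3x3 -> narrow bottleneck, 1x1 -> full width, skip
add) and then doubles spatial resolution with parameter-free bilinear
upsampling, so starting from the S/8-sized shared feature map F the branch
emits maps at S/4, S/2 and S.

Cross-connection: after stage k, each branch's input to stage k+1 is the
element-wise sum of its own stage-k output and the other branch's stage-k
output.  Summation (rather than concatenation) keeps every block at the
declared channel width.  The edge branch thereby sees dense region evidence
and the mask branch sees boundary evidence, coupling the two tasks during
both forward prediction and backpropagation.
"""

from __future__ import annotations

from . import nn
from .config import NetConfig


class ResidualUpBlock(nn.Module):
    """Channel-preserving residual block followed by 2x bilinear upsampling."""

    def __init__(self, channels: int, bottleneck: int):
        super().__init__()
        self.conv_in = nn.conv_bn_relu(channels, channels, 1)
        self.conv_mid = nn.conv_bn_relu(channels, bottleneck, 3, padding=1)
        self.conv_out = nn.Sequential(
            nn.Conv2d(bottleneck, channels, 1, bias=False),
            nn.BatchNorm2d(channels),
        )
        self.up = nn.UpsampleBilinear(2)

    def forward(self, x):
        h = self.conv_out(self.conv_mid(self.conv_in(x)))
        return self.up(h + x)


class CCLDecoder(nn.Module):
    """The pair of cross-connected branches; ``use_edge=False`` drops the edge
    subnet and all cross-connections (the structural ablation baseline)."""

    STAGES = 3

    def __init__(self, cfg: NetConfig, use_edge: bool = True):
        super().__init__()
        ch = cfg.feature_channels
        bottleneck = max(1, cfg.scaled(cfg.decoder_bottleneck))
        self.use_edge = use_edge
        self.seg_blocks = nn.ModuleList(
            ResidualUpBlock(ch, bottleneck) for _ in range(self.STAGES)
        )
        if use_edge:
            self.edge_blocks = nn.ModuleList(
                ResidualUpBlock(ch, bottleneck) for _ in range(self.STAGES)
            )

    def forward(self, feat):
        """Return ``(seg_pyramid, edge_pyramid)``; the edge pyramid is ``None``
        when the edge subnet is ablated."""
        seg_pyr = []
        if not self.use_edge:
            x = feat
            for block in self.seg_blocks:
                x = block(x)
                seg_pyr.append(x)
            return seg_pyr, None
        edge_pyr = []
        s_in = e_in = feat
        for k in range(self.STAGES):
            s = self.seg_blocks[k](s_in)
            e = self.edge_blocks[k](e_in)
            seg_pyr.append(s)
            edge_pyr.append(e)
            fused = s + e  # cross-connection: each task feeds the other
            s_in = e_in = fused
        return seg_pyr, edge_pyr
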