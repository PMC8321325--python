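"""The full segmentation network and its ablation variants.

Three constructible configurations mirror the ablation study:

``seg_only``
    backbone + Seg subnet + direct 1x1 head (no edge branch, no
    cross-connections) — the structural baseline.
``seg_edge``
    backbone + both cross-connected subnets, but a direct 1x1 head instead of
    multi-scale aggregation.
``full``
    backbone + both subnets + the shared MSFA head.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .backbone import build_backbone
from .branches import CCLDecoder
from .config import ABLATION_MODES, ConfigError, NetConfig
from .msfa import DirectHead, MSFAHead


class LesionNet(nn.Module):
    def __init__(self, cfg: NetConfig, mode: str = "full", dilate_conv4: bool = True):
        super().__init__()
        if mode not in ABLATION_MODES:
            raise ConfigError(f"mode must be one of {ABLATION_MODES}, got {mode!r}")
        self.cfg = cfg
        self.mode = mode
        self.backbone = build_backbone(cfg, dilate_conv4=dilate_conv4)
        self.decoder = CCLDecoder(cfg, use_edge=(mode != "seg_only"))
        # one head instance shared between the two branches
        self.head = MSFAHead(cfg) if mode == "full" else DirectHead(cfg)

    def forward(self, x):
        """Return ``{"seg": prob map, "edge": prob map or None}``."""
        feat = self.backbone(x)
        seg_pyr, edge_pyr = self.decoder(feat)
        out = {"seg": self.head(seg_pyr)}
        out["edge"] = self.head(edge_pyr) if edge_pyr is not None else None
        return out

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Segmentation probabilities for a float (N,3,S,S) batch, eval mode,
        no autodiff graph."""
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                probs = self.forward(np.asarray(images, dtype=np.float32))["seg"].data
        finally:
            if was_training:
                self.train()
        return probs[:, 0]


def build_model(cfg: NetConfig, mode: str = "full", seed: int | None = None) -> LesionNet:
    """Construct a network, optionally with deterministic weight init."""
    if seed is not None:
        nn.seed_init(seed)
    return LesionNet(cfg, mode=mode)
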