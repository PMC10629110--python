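"""Segmentation decoder: cascaded 2x upsampling with skip fusion.

Each up-block applies a stride-2 transposed convolution to the deeper
map, concatenates the encoder skip at the target resolution along the
channel axis, and mixes with a conv3x3 + BN + ReLU unit.  Four blocks
climb from level 4 back to level 0, where a 1x1 convolution and a sigmoid
produce the full-resolution foreground-probability map (single channel:
the losses are written over one probability per pixel).
"""

from __future__ import annotations

from . import nn
from .config import NetworkConfig
from .nn import Tensor, concat, sigmoid

__all__ = ["UpBlock", "Decoder"]


class UpBlock(nn.Module):
    """level-L map + level-(L-1) skip -> fused level-(L-1) map."""

    def __init__(self, rng, in_ch: int, skip_ch: int, out_ch: int):
        super().__init__()
        self.up = nn.ConvTranspose2d(rng, in_ch, out_ch, stride=2)
        self.fuse = nn.ConvBnRelu(rng, out_ch + skip_ch, out_ch)

    def forward(self, f: Tensor, skip: Tensor) -> Tensor:
        up = self.up(f)
        if up.shape[-2:] != skip.shape[-2:]:
            raise ValueError(
                f"skip resolution {skip.shape[-2:]} does not match "
                f"upsampled map {up.shape[-2:]}"
            )
        return self.fuse(concat([up, skip], axis=1))


class Decoder(nn.Module):
    """Five encoder maps -> (N, 1, H, W) sigmoid probability map."""

    def __init__(self, rng, cfg: NetworkConfig):
        super().__init__()
        ch = cfg.stage_channels
        for lvl in range(4, 0, -1):
            self.add_module(f"up{lvl}", UpBlock(rng, ch[lvl], ch[lvl - 1], ch[lvl - 1]))
        self.out_conv = nn.Conv2d(rng, ch[0], 1, 1)
        # bias the output toward the foreground prior (lesions cover a few
        # percent of a slice) so early training is not dominated by the
        # easy background — the standard focal-loss initialization
        self.out_conv.bias.data[:] = -3.5

    def forward(self, features: list[Tensor]) -> Tensor:
        if len(features) != 5:
            raise ValueError(f"expected 5 feature levels, got {len(features)}")
        x = features[4]
        for lvl in range(4, 0, -1):
            x = self._modules[f"up{lvl}"](x, features[lvl - 1])
        return sigmoid(self.out_conv(x))
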