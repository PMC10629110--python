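"""Shared encoder: multi-scale attention (MSA) modules and the 5-level pyramid.

The MSA module builds a convolutional attention map from a local 3x3
convolution plus three parallel strip-convolution branches (a k x 1
followed by a 1 x k depth-wise pair approximates a k x k kernel at linear
cost) applied to a shared 5x5 depth-wise convolution of the input.  A 1x1
convolution mixes the sum across channels and the result reweights the
input element-wise:

    Att = Conv1x1( Conv3x3(F) + sum_i Branch_i(DWConv(F)) )
    Out = Att * F

One MSA block is a conv3x3 -> batch-norm -> ReLU unit followed by an MSA
module.  The encoder stacks one block per resolution level with stride-2
convolutions in between, halving the spatial side and (by default)
doubling the width at each of levels 1..4, so a 384-pixel input ends at a
24x24 map that feeds the genotype classifier while all five levels feed
the decoder skips.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import NetworkConfig
from .nn import Tensor

__all__ = ["MsaLayer", "MsaBlock", "Encoder"]


class MsaLayer(nn.Module):
    """Channel-preserving attention reweighting (see module docstring)."""

    def __init__(self, rng, channels: int, branch_kernels=(5, 7, 11), dw_kernel: int = 5):
        super().__init__()
        self.local_conv = nn.Conv2d(rng, channels, channels, 3)
        self.shared_dw = nn.Conv2d(rng, channels, channels, dw_kernel, groups=channels)
        for i, k in enumerate(branch_kernels):
            self.add_module(f"branch{i}_v", nn.Conv2d(rng, channels, channels, (k, 1),
                                                      groups=channels))
            self.add_module(f"branch{i}_h", nn.Conv2d(rng, channels, channels, (1, k),
                                                      groups=channels))
        self.n_branches = len(branch_kernels)
        self.mix_1x1 = nn.Conv2d(rng, channels, channels, 1)
        # start the gate near identity (Att ~ 1) so features and gradients
        # flow through the multiplicative reweighting from the first step
        self.mix_1x1.bias.data[:] = 1.0

    def forward(self, f: Tensor) -> Tensor:
        att = self.local_conv(f)
        shared = self.shared_dw(f)
        for i in range(self.n_branches):
            v = self._modules[f"branch{i}_v"](shared)
            att = att + self._modules[f"branch{i}_h"](v)
        att = self.mix_1x1(att)
        return att * f


class MsaBlock(nn.Module):
    """conv3x3 + BN + ReLU entry unit, then the MSA attention module."""

    def __init__(self, rng, in_ch: int, out_ch: int, branch_kernels=(5, 7, 11),
                 dw_kernel: int = 5):
        super().__init__()
        self.entry = nn.ConvBnRelu(rng, in_ch, out_ch)
        self.msa = MsaLayer(rng, out_ch, branch_kernels, dw_kernel)

    def forward(self, x: Tensor) -> Tensor:
        return self.msa(self.entry(x))


class Encoder(nn.Module):
    """Five-level feature pyramid; level L has side input_size / 2**L."""

    def __init__(self, rng, cfg: NetworkConfig):
        super().__init__()
        ch = cfg.stage_channels
        bk, dk = tuple(cfg.branch_kernels), cfg.dw_kernel
        self.add_module("stage0", MsaBlock(rng, 1, ch[0], bk, dk))
        for lvl in range(1, 5):
            self.add_module(f"down{lvl}",
                            nn.ConvBnRelu(rng, ch[lvl - 1], ch[lvl], kernel=3, stride=2))
            self.add_module(f"stage{lvl}", MsaBlock(rng, ch[lvl], ch[lvl], bk, dk))
        self.input_size = cfg.input_size

    def forward(self, x: Tensor) -> list[Tensor]:
        """Map an (N, 1, H, W) batch to feature maps at levels 0..4."""
        h, w = x.shape[-2:]
        if h != w or h % 16 != 0:
            raise ValueError(f"input must be square with side divisible by 16, got {h}x{w}")
        feats = [self._modules["stage0"](x)]
        for lvl in range(1, 5):
            down = self._modules[f"down{lvl}"](feats[-1])
            feats.append(self._modules[f"stage{lvl}"](down))
        return feats


def as_batch(images: np.ndarray) -> Tensor:
    """Stack (H, W) or (N, H, W) float images into an (N, 1, H, W) Tensor."""
    arr = np.asarray(images, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    return Tensor(arr[:, None])
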