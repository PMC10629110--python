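"""Network, loss and training configuration with validation and YAML I/O.

The defaults reproduce the published operating point: 384x384 inputs, a
five-level encoder, strip-convolution kernels (5, 7, 11), focal-loss
balance alpha = 0.8 and focusing gamma = 2, focal scale beta = 1/25000,
uncertainty-based task weighting, Adam at 3e-4 and patience-20 early
stopping.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["NetworkConfig", "validate_config", "phantom_config"]


@dataclass
class NetworkConfig:
    """All architecture / loss / training hyperparameters.

    Attributes
    ----------
    input_size : int
        Side of the square input slice in pixels; must divide by 16
        (four 2x downsamplings below the full-resolution stage).
    stage_channels : list[int]
        Encoder widths at resolution levels 0..4; the deepest width is the
        transformer embedding dimension.
    branch_kernels : list[int]
        Strip-convolution lengths of the three multi-scale attention
        branches (odd, so 'same' padding is symmetric).
    dw_kernel : int
        Kernel of the shared depth-wise convolution feeding the branches.
    num_heads : int
        Attention heads; must divide the deepest channel count.
    patch_grid : int
        The deepest feature map is split into ``patch_grid**2`` patches,
        each flattened to a token sequence for the transformer block.
    pool_kernel : int
        Average-pooling kernel/stride applied after the transformer block.
    ff_mult, mlp_hidden : int
        Feed-forward expansion inside the transformer block and hidden
        width of the classification MLP head.
    focal_alpha, focal_gamma, focal_scale_beta : float
        Focal-loss balance/focusing parameters and the scale that brings
        the pixel-summed focal loss to the magnitude of the Dice loss.
    weighting_mode : str
        'uncertainty' (learned homoscedastic task weights) or 'equal'
        (fixed 0.5/0.5 ablation).
    seg_threshold, class_threshold : float
        Binarization threshold for the probability map, and the strict
        cut-off for calling a patient mutant.
    """

    input_size: int = 384
    stage_channels: list[int] = field(default_factory=lambda: [32, 64, 128, 256, 512])
    branch_kernels: list[int] = field(default_factory=lambda: [5, 7, 11])
    dw_kernel: int = 5
    num_heads: int = 8
    patch_grid: int = 4
    pool_kernel: int = 4
    ff_mult: int = 4
    mlp_hidden: int = 64
    focal_alpha: float = 0.8
    focal_gamma: float = 2.0
    focal_scale_beta: float = 1.0 / 25000.0
    weighting_mode: str = "uncertainty"
    learning_rate: float = 3e-4
    batch_size: int = 8
    max_epochs: int = 100
    patience: int = 20
    dice_epsilon: float = 1e-6
    seed: int = 0
    seg_threshold: float = 0.5
    class_threshold: float = 0.5

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def validate_config(cfg: NetworkConfig) -> NetworkConfig:
    """Check every structural invariant; return ``cfg`` unchanged if valid.

    Raises
    ------
    ValueError
        Naming the violated invariant.
    """
    if cfg.input_size % 16 != 0:
        raise ValueError(f"input_size not divisible by 16 (got {cfg.input_size})")
    if len(cfg.stage_channels) != 5:
        raise ValueError(
            f"stage_channels must list 5 widths (got {len(cfg.stage_channels)})"
        )
    if any(c <= 0 for c in cfg.stage_channels):
        raise ValueError("stage_channels must be positive")
    if cfg.stage_channels[-1] % cfg.num_heads != 0:
        raise ValueError(
            f"channels not divisible by heads "
            f"({cfg.stage_channels[-1]} % {cfg.num_heads} != 0)"
        )
    deepest = cfg.input_size // 16
    if deepest % cfg.patch_grid != 0:
        raise ValueError(
            f"deepest map side {deepest} not divisible by patch_grid {cfg.patch_grid}"
        )
    if deepest % cfg.pool_kernel != 0:
        raise ValueError(
            f"deepest map side {deepest} not divisible by pool_kernel {cfg.pool_kernel}"
        )
    if len(cfg.branch_kernels) != 3:
        raise ValueError("branch_kernels must list exactly 3 kernels")
    if any(k % 2 == 0 for k in cfg.branch_kernels):
        raise ValueError(f"branch kernels must be odd (got {cfg.branch_kernels})")
    if cfg.dw_kernel % 2 == 0:
        raise ValueError(f"dw_kernel must be odd (got {cfg.dw_kernel})")
    if not (0.0 < cfg.focal_alpha < 1.0):
        raise ValueError(f"focal_alpha must lie in (0,1) (got {cfg.focal_alpha})")
    if cfg.focal_gamma < 0:
        raise ValueError(f"focal_gamma must be >= 0 (got {cfg.focal_gamma})")
    if cfg.weighting_mode not in ("uncertainty", "equal"):
        raise ValueError(f"weighting_mode must be 'uncertainty' or 'equal' "
                         f"(got {cfg.weighting_mode!r})")
    if cfg.dice_epsilon <= 0:
        raise ValueError("dice_epsilon must be > 0")
    if cfg.learning_rate <= 0:
        raise ValueError("learning_rate must be > 0")
    if cfg.patience < 1:
        raise ValueError("patience must be >= 1")
    return cfg


def phantom_config(**overrides) -> NetworkConfig:
    """A desk-scale configuration for 96x96 phantom slices.

    96/16 = 6 at the deepest level, so the patch grid is 2 (3x3-pixel
    patches of 9 tokens) and the pooling kernel 3.  Encoder widths are
    kept small; the deepest width 64 still divides 8 heads.
    """
    base = dict(
        input_size=96,
        stage_channels=[8, 16, 32, 64, 64],
        patch_grid=2,
        pool_kernel=3,
        mlp_hidden=32,
        batch_size=8,
    )
    base.update(overrides)
    return validate_config(NetworkConfig(**base))
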