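"""Training objectives: Dice, focal, their combination, cross-entropy, and
the uncertainty-weighted joint loss.

Segmentation loss
-----------------
    L_GTV = L_Dice + beta * L_Focal

``L_Dice = 1 - 2 sum(p y) / (sum(p + y) + eps)`` measures shape overlap;
``L_Focal = -sum_i alpha_i (1 - p_t,i)^gamma log(p_t,i)`` is cross-entropy
down-weighted on easy pixels, SUMMED over pixels (p_t is the predicted
probability of the true class; alpha_i = alpha on foreground, 1 - alpha on
background).  Because the pixel sum is orders of magnitude larger than the
Dice term, beta defaults to 1/25000 to bring both to the same level.

Joint loss
----------
In 'uncertainty' mode the two task losses are combined through learnable
homoscedastic-uncertainty weights:

    L_joint = L_GTV / (2 sigma_GTV^2) + L_EGFR / (2 sigma_EGFR^2)
              + log(sigma_GTV * sigma_EGFR)

with both sigmas initialized to 1 and learned jointly with the network
(internally parameterized as s = log sigma^2 for positivity).  'equal'
mode is the fixed ablation 0.5 * L_GTV + 0.5 * L_EGFR.

All functions accept either plain numpy arrays / floats (returning a
float) or autodiff Tensors (returning a Tensor on the graph).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import NetworkConfig
from .nn import Tensor, clip, exp, log

__all__ = [
    "PROB_FLOOR",
    "UncertaintyParams",
    "LossBreakdown",
    "dice_loss",
    "focal_loss",
    "seg_loss",
    "ce_loss",
    "joint_loss",
]

#: probabilities are clamped to [PROB_FLOOR, 1 - PROB_FLOOR] before any log
PROB_FLOOR = 1e-7


def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def _ret(t: Tensor, was_tensor: bool):
    return t if was_tensor else float(t.data)


class UncertaintyParams:
    """Learnable per-task uncertainty, stored as s = log sigma^2.

    sigma_gtv / sigma_egfr start at 1 (s = 0); ``tensors`` exposes the
    underlying parameters for the optimizer.
    """

    def __init__(self, sigma_gtv: float = 1.0, sigma_egfr: float = 1.0):
        if sigma_gtv <= 0 or sigma_egfr <= 0:
            raise ValueError("sigma values must be strictly positive")
        self.s_gtv = Tensor(np.array(2.0 * np.log(sigma_gtv)), requires_grad=True)
        self.s_egfr = Tensor(np.array(2.0 * np.log(sigma_egfr)), requires_grad=True)

    @property
    def sigma_gtv(self) -> float:
        return float(np.exp(0.5 * self.s_gtv.data))

    @property
    def sigma_egfr(self) -> float:
        return float(np.exp(0.5 * self.s_egfr.data))

    def tensors(self) -> list[Tensor]:
        return [self.s_gtv, self.s_egfr]


@dataclass
class LossBreakdown:
    """All scalar loss components of one step/epoch."""

    l_dice: float
    l_focal: float
    l_gtv: float
    l_egfr: float
    l_joint: float
    sigma_gtv: float = 1.0
    sigma_egfr: float = 1.0


def _check_seg_inputs(p, y):
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs y {y.shape}")
    if np.any(p.data < 0) or np.any(p.data > 1):
        raise ValueError("probabilities must lie in [0, 1]")


def dice_loss(p, y, epsilon: float = 1e-6):
    """1 - 2 sum(p y) / (sum(p + y) + eps); 0 for perfect overlap."""
    p, pt = _as_tensor(p)
    y, _ = _as_tensor(y)
    _check_seg_inputs(p, y)
    inter = (p * y).sum()
    denom = (p + y).sum() + epsilon
    return _ret(1.0 - (2.0 * inter) / denom, pt)


def focal_loss(p, y, alpha: float = 0.8, gamma: float = 2.0):
    """Pixel-summed focal loss with the two-sided p_t convention."""
    p, pt = _as_tensor(p)
    y, _ = _as_tensor(y)
    _check_seg_inputs(p, y)
    p_t = p * y + (1.0 - p) * (1.0 - y)
    p_t = clip(p_t, PROB_FLOOR, 1.0)
    alpha_i = alpha * y.data + (1.0 - alpha) * (1.0 - y.data)
    loss = -(Tensor(alpha_i) * (1.0 - p_t) ** gamma * log(p_t)).sum()
    return _ret(loss, pt)


def seg_loss(p, y, cfg: NetworkConfig):
    """(l_gtv, l_dice, l_focal) with l_gtv = l_dice + beta * l_focal."""
    l_dice = dice_loss(p, y, cfg.dice_epsilon)
    l_focal = focal_loss(p, y, cfg.focal_alpha, cfg.focal_gamma)
    return l_dice + cfg.focal_scale_beta * l_focal, l_dice, l_focal


def ce_loss(q, label):
    """Cross-entropy -log q[label], batch-averaged.

    ``q`` is (2,) or (N, 2) class probabilities (wild, mutant); ``label``
    a scalar or length-N vector in {0, 1}.
    """
    q, qt = _as_tensor(q)
    labels = np.atleast_1d(np.asarray(label, dtype=int))
    q2 = q.reshape(-1, 2)
    if not np.allclose(q2.data.sum(axis=-1), 1.0, atol=1e-5):
        raise ValueError("class probabilities must sum to 1")
    onehot = np.zeros(q2.shape)
    onehot[np.arange(len(labels)), labels] = 1.0
    picked = clip((q2 * Tensor(onehot)).sum(axis=-1), PROB_FLOOR, 1.0)
    return _ret(-log(picked).mean(), qt)


def joint_loss(l_gtv, l_egfr, u: UncertaintyParams | None = None,
               mode: str = "uncertainty"):
    """Combine the two task losses (see module docstring)."""
    g, gt = _as_tensor(l_gtv)
    e, et = _as_tensor(l_egfr)
    if mode == "equal":
        return _ret(0.5 * g + 0.5 * e, gt or et)
    if mode != "uncertainty":
        raise ValueError(f"unknown weighting mode {mode!r}")
    if u is None:
        raise ValueError("uncertainty mode requires UncertaintyParams")
    total = (
        0.5 * exp(-u.s_gtv) * g
        + 0.5 * exp(-u.s_egfr) * e
        + 0.5 * (u.s_gtv + u.s_egfr)
    )
    return _ret(total, gt or et)
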