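"""The full multi-task network: shared encoder, two task heads."""

from __future__ import annotations

import numpy as np

from . import nn
from .backbone import Encoder, as_batch
from .classifier import ClassifierHead
from .config import NetworkConfig, validate_config
from .data import SlicePrediction
from .decoder import Decoder
from .nn import Tensor

__all__ = ["MultiTaskNet", "SingleTaskNet"]


class MultiTaskNet(nn.Module):
    """Encoder + segmentation decoder + genotype classifier.

    ``forward`` returns the (N, 1, H, W) foreground-probability map and
    the (N, 2) classification logits; :meth:`predict_slices` wraps a
    batch of raw slices into :class:`~msanet.data.SlicePrediction`.
    """

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator | None = None):
        super().__init__()
        validate_config(cfg)
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.encoder = Encoder(rng, cfg)
        self.decoder = Decoder(rng, cfg)
        self.head = ClassifierHead(rng, cfg)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        feats = self.encoder(x)
        return self.decoder(feats), self.head.logits(feats[4])

    def predict_slices(self, images: np.ndarray) -> list[SlicePrediction]:
        """Inference on (N, H, W) normalized slices (no gradients kept)."""
        was_training = self.training
        self.eval()
        try:
            seg, logits = self.forward(as_batch(images))
            probs = nn.softmax(Tensor(logits.data), axis=-1).data
        finally:
            self.train(was_training)
        out = []
        for i in range(seg.data.shape[0]):
            p = seg.data[i, 0]
            out.append(SlicePrediction(
                seg_prob=p,
                seg_mask=(p > self.cfg.seg_threshold).astype(np.uint8),
                mutation_prob=float(probs[i, 1]),
                slice_index=i,
            ))
        return out


class SingleTaskNet(nn.Module):
    """Encoder + classifier only — the no-decoder ablation baseline."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator | None = None):
        super().__init__()
        validate_config(cfg)
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.encoder = Encoder(rng, cfg)
        self.head = ClassifierHead(rng, cfg)

    def forward(self, x: Tensor) -> tuple[None, Tensor]:
        feats = self.encoder(x)
        return None, self.head.logits(feats[4])
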