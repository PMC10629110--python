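"""Training and inference loop.

Optimization follows the published protocol: one Adam optimizer (initial
learning rate 3e-4) over all network weights AND the two uncertainty
parameters, joint loss as the error measure, and early stopping when the
validation joint loss has not improved for ``patience`` (default 20)
epochs.  The validation loss is computed with the current sigmas frozen so
epochs stay comparable.  The checkpoint returned is the one with the best
validation loss.

Slices are shuffled across patients each epoch; the split, the shuffle
and the weight initialization all derive from explicit seeds, so a run is
reproducible on one platform.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregate import SliceEvidence, aggregate_patient
from .backbone import as_batch
from .config import NetworkConfig
from .data import EvalReport, PatientCase
from .losses import PROB_FLOOR, UncertaintyParams
from .metrics import classification_report, dice_score, hd95_flagged, \
    pixel_precision_recall
from .model import MultiTaskNet
from .nn import Adam, Tensor, clip, log, log_softmax

__all__ = ["split_cohort", "train", "predict_patient", "evaluate_cohort",
           "TrainHistory", "EarlyStopper", "zscore"]


def zscore(image: np.ndarray) -> np.ndarray:
    """Per-slice intensity normalization to zero mean, unit variance."""
    img = np.asarray(image, dtype=np.float32)
    return (img - img.mean()) / max(float(img.std()), 1e-6)


@dataclass
class TrainHistory:
    """Per-epoch loss records plus the index of the best checkpoint."""

    frame: pd.DataFrame
    best_epoch: int
    best_val: float


class EarlyStopper:
    """Stop when the monitored value has not improved for ``patience``
    epochs; 'improved' means lower than the running best by >= ``min_delta``."""

    def __init__(self, patience: int, min_delta: float = 1e-6):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.best_epoch = -1
        self._since = 0

    def update(self, epoch: int, value: float) -> bool:
        """Record ``value``; return True if training should stop."""
        if value < self.best - self.min_delta:
            self.best = value
            self.best_epoch = epoch
            self._since = 0
        else:
            self._since += 1
        return self._since >= self.patience


def split_cohort(cohort: list[PatientCase], n_val: int, seed: int
                 ) -> tuple[list[PatientCase], list[PatientCase]]:
    """Seeded patient-level split into (train, validation)."""
    if n_val >= len(cohort):
        raise ValueError(f"n_val={n_val} must be < cohort size {len(cohort)}")
    order = np.random.default_rng(seed).permutation(len(cohort))
    val_idx = set(order[:n_val].tolist())
    train = [c for i, c in enumerate(cohort) if i not in val_idx]
    val = [c for i, c in enumerate(cohort) if i in val_idx]
    return train, val


def _stack_slices(cohort: list[PatientCase]):
    images, masks, labels = [], [], []
    for case in cohort:
        for s in case.slices:
            images.append(zscore(s.image))
            masks.append(s.mask.astype(np.float32))
            labels.append(s.genotype)
    return (np.stack(images), np.stack(masks), np.array(labels, dtype=int))


def _batch_losses(model, images, masks, labels, cfg: NetworkConfig):
    """Forward one batch; per-sample Dice/focal averaged over the batch."""
    seg, logits = model(as_batch(images))
    # classification: mean cross-entropy from log-softmax of the logits
    logp = log_softmax(logits, axis=-1)
    onehot = np.zeros((len(labels), 2))
    onehot[np.arange(len(labels)), labels] = 1.0
    l_egfr = -(logp * Tensor(onehot)).sum(axis=-1).mean()
    if seg is None:  # classification-only ablation
        return None, None, l_egfr
    y = Tensor(masks[:, None])
    p = clip(seg, PROB_FLOOR, 1.0 - PROB_FLOOR)
    inter = (p * y).sum(axis=(1, 2, 3))
    denom = (p + y).sum(axis=(1, 2, 3)) + cfg.dice_epsilon
    l_dice = (1.0 - 2.0 * inter / denom).mean()
    p_t = p * y + (1.0 - p) * (1.0 - y)
    alpha_i = cfg.focal_alpha * y.data + (1.0 - cfg.focal_alpha) * (1.0 - y.data)
    l_focal = (-(Tensor(alpha_i) * (1.0 - p_t) ** cfg.focal_gamma * log(p_t))
               .sum(axis=(1, 2, 3)).mean())
    return l_dice, l_focal, l_egfr


def _joint(l_gtv, l_egfr, u: UncertaintyParams, cfg: NetworkConfig,
           freeze_sigma: bool = False):
    if l_gtv is None:
        return l_egfr
    if cfg.weighting_mode == "equal":
        return 0.5 * l_gtv + 0.5 * l_egfr
    if freeze_sigma:
        wg = 0.5 * np.exp(-float(u.s_gtv.data))
        we = 0.5 * np.exp(-float(u.s_egfr.data))
        pen = 0.5 * (float(u.s_gtv.data) + float(u.s_egfr.data))
        return wg * l_gtv + we * l_egfr + pen
    from .losses import joint_loss

    return joint_loss(l_gtv, l_egfr, u, mode="uncertainty")


def _epoch_eval_loss(model, arrays, u, cfg) -> float:
    """Joint loss over a set, eval mode, sigmas frozen."""
    images, masks, labels = arrays
    model.eval()
    total, n = 0.0, 0
    for lo in range(0, len(images), cfg.batch_size):
        sl = slice(lo, lo + cfg.batch_size)
        l_dice, l_focal, l_egfr = _batch_losses(model, images[sl], masks[sl],
                                                labels[sl], cfg)
        l_gtv = None if l_dice is None else l_dice + cfg.focal_scale_beta * l_focal
        j = _joint(l_gtv, l_egfr, u, cfg, freeze_sigma=True)
        k = len(labels[sl])
        total += float(j.data) * k
        n += k
    model.train()
    return total / n


def train(model, train_set: list[PatientCase], val_set: list[PatientCase],
          cfg: NetworkConfig, run_dir=None, verbose: bool = False,
          task_loss_scales: tuple[float, float] = (1.0, 1.0)):
    """Fit ``model``; returns (best_state_dict, TrainHistory).

    The model is left loaded with the best-validation weights.  If
    ``run_dir`` is given, the config, per-epoch history table, log file
    and best checkpoint are written there.  ``task_loss_scales``
    multiplies (L_GTV, L_EGFR) before weighting — a diagnostic knob for
    studying how the uncertainty weights adapt to task magnitude.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    tr = _stack_slices(train_set)
    va = _stack_slices(val_set)
    u = UncertaintyParams()
    params = list(model.parameters())
    if getattr(model, "decoder", None) is not None and cfg.weighting_mode == "uncertainty":
        params += u.tensors()
    opt = Adam(params, lr=cfg.learning_rate)
    stopper = EarlyStopper(cfg.patience)
    best_state = model.state_dict()
    rows, log_lines = [], []
    n_slices = len(tr[0])
    t0 = time.time()
    for epoch in range(cfg.max_epochs):
        order = np.random.default_rng([cfg.seed, epoch]).permutation(n_slices)
        sums = dict.fromkeys(("l_dice", "l_focal", "l_gtv", "l_egfr", "l_joint"), 0.0)
        n_seen = 0
        for lo in range(0, n_slices, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            l_dice, l_focal, l_egfr = _batch_losses(
                model, tr[0][idx], tr[1][idx], tr[2][idx], cfg
            )
            l_gtv = None if l_dice is None else l_dice + cfg.focal_scale_beta * l_focal
            sg, se = task_loss_scales
            if sg != 1.0 and l_gtv is not None:
                l_gtv = l_gtv * sg
            if se != 1.0:
                l_egfr = l_egfr * se
            l_joint = _joint(l_gtv, l_egfr, u, cfg)
            if not np.isfinite(float(l_joint.data)):
                raise RuntimeError(
                    f"training diverged: non-finite joint loss at epoch {epoch}"
                )
            opt.zero_grad()
            l_joint.backward()
            opt.step()
            k = len(idx)
            n_seen += k
            sums["l_egfr"] += float(l_egfr.data) * k
            sums["l_joint"] += float(l_joint.data) * k
            if l_dice is not None:
                sums["l_dice"] += float(l_dice.data) * k
                sums["l_focal"] += float(l_focal.data) * k
                sums["l_gtv"] += float(l_gtv.data) * k
        means = {key: val / n_seen for key, val in sums.items()}
        val_loss = _epoch_eval_loss(model, va, u, cfg)
        rows.append({"epoch": epoch, **means, "sigma_gtv": u.sigma_gtv,
                     "sigma_egfr": u.sigma_egfr, "val_loss": val_loss})
        line = (f"epoch {epoch:3d}  joint {means['l_joint']:.4f}  "
                f"val {val_loss:.4f}  sigma ({u.sigma_gtv:.3f}, {u.sigma_egfr:.3f})")
        log_lines.append(line)
        if verbose:
            print(line, flush=True)
        stop = stopper.update(epoch, val_loss)
        if stopper.best_epoch == epoch:
            best_state = model.state_dict()
        if stop:
            break
    model.load_state_dict(best_state)
    history = TrainHistory(frame=pd.DataFrame(rows),
                           best_epoch=stopper.best_epoch, best_val=stopper.best)
    if run_dir is not None:
        from pathlib import Path

        d = Path(run_dir)
        d.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(d / "config.yaml")
        history.frame.to_csv(d / "history.csv", index=False)
        np.savez(d / "checkpoint.npz", **best_state)
        (d / "train.log").write_text(
            "\n".join(log_lines) + f"\nbest_epoch {stopper.best_epoch}"
            f"\nwall_time_s {time.time() - t0:.1f}\n"
        )
    return best_state, history


def predict_patient(model: MultiTaskNet, patient: PatientCase,
                    cfg: NetworkConfig):
    """(per-slice predictions, patient call) for one slice stack."""
    images = np.stack([zscore(s.image) for s in patient.slices])
    preds = []
    for lo in range(0, len(images), cfg.batch_size):
        preds.extend(model.predict_slices(images[lo : lo + cfg.batch_size]))
    for pred, s in zip(preds, patient.slices):
        pred.slice_index = s.slice_index
    evidence = [SliceEvidence.from_prediction(p) for p in preds]
    call = aggregate_patient(evidence, threshold=cfg.class_threshold,
                             patient_id=patient.patient_id)
    return preds, call


def evaluate_cohort(model: MultiTaskNet, cohort: list[PatientCase],
                    cfg: NetworkConfig, spacing=(1.0, 1.0)) -> EvalReport:
    """Slice-level segmentation metrics + patient-level classification."""
    dices, hd95s, precs, recs = [], [], [], []
    n_degenerate = 0
    calls, truths = [], []
    rows = []
    for case in cohort:
        preds, call = predict_patient(model, case, cfg)
        for pred, s in zip(preds, case.slices):
            dices.append(dice_score(pred.seg_mask, s.mask))
            hd, degenerate = hd95_flagged(pred.seg_mask, s.mask, spacing)
            if degenerate:
                n_degenerate += 1
            else:
                hd95s.append(hd)
            p, r = pixel_precision_recall(pred.seg_mask, s.mask)
            precs.append(p)
            recs.append(r)
        calls.append(call)
        truths.append(case.genotype)
        rows.append({"patient_id": case.patient_id, "true": case.genotype,
                     "pred": call.label, "mean_prob": call.mean_prob})
    acc, prec, rec, f1 = classification_report([c.label for c in calls], truths)
    report = EvalReport(
        seg={
            "dice": float(np.mean(dices)),
            "hd95": float(np.mean(hd95s)) if hd95s else float("nan"),
            "hd95_degenerate_slices": n_degenerate,
            "pixel_precision": float(np.mean(precs)),
            "pixel_recall": float(np.mean(recs)),
        },
        cls={"accuracy": acc, "precision": prec, "recall": rec, "f1": f1},
        per_patient=pd.DataFrame(rows),
    )
    return report
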