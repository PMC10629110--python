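"""Training engine: splits, stopping rule, seeded runs, checkpoints."""

import numpy as np
import pytest

from msanet import MultiTaskNet, generate_cohort, split_cohort
from msanet.train import EarlyStopper, predict_patient, train, zscore


def test_zscore_normalizes_each_slice():
    rng = np.random.default_rng(50)
    img = rng.normal(3.0, 2.0, size=(32, 32))
    z = zscore(img)
    assert abs(z.mean()) < 1e-5 and abs(z.std() - 1.0) < 1e-4


class TestSplit:
    def test_patient_level_disjoint_split(self, tiny_cohort):
        tr, va = split_cohort(tiny_cohort, 3, seed=0)
        assert len(tr) == 7 and len(va) == 3
        assert not {c.patient_id for c in tr} & {c.patient_id for c in va}

    def test_same_seed_same_split(self, tiny_cohort):
        a = split_cohort(tiny_cohort, 3, seed=5)
        b = split_cohort(tiny_cohort, 3, seed=5)
        assert [c.patient_id for c in a[0]] == [c.patient_id for c in b[0]]

    def test_full_holdout_rejected(self, tiny_cohort):
        with pytest.raises(ValueError, match="must be <"):
            split_cohort(tiny_cohort, len(tiny_cohort), seed=0)


class TestEarlyStopper:
    def test_improving_then_flat_stops_after_patience(self):
        stopper = EarlyStopper(patience=20)
        losses = [1.0 - 0.1 * e for e in range(6)] + [0.5] * 40
        stopped_at = None
        for epoch, v in enumerate(losses):
            if stopper.update(epoch, v):
                stopped_at = epoch
                break
        assert stopper.best_epoch == 5
        assert stopped_at == 25

    def test_improvement_needs_min_delta(self):
        stopper = EarlyStopper(patience=2, min_delta=1e-6)
        assert not stopper.update(0, 1.0)
        assert not stopper.update(1, 1.0 - 1e-9)  # not an improvement
        assert stopper.update(2, 1.0 - 1e-8)
        assert stopper.best_epoch == 0


@pytest.fixture(scope="module")
def trained(tiny_cfg, tiny_cohort):
    tr, va = split_cohort(tiny_cohort, 3, seed=1)
    model = MultiTaskNet(tiny_cfg, np.random.default_rng(tiny_cfg.seed))
    state, history = train(model, tr, va, tiny_cfg)
    return model, state, history, tr, va


def test_history_schema_and_stopping_invariant(trained, tiny_cfg):
    _, _, history, _, _ = trained
    frame = history.frame
    for col in ("l_dice", "l_focal", "l_gtv", "l_egfr", "l_joint",
                "sigma_gtv", "sigma_egfr", "val_loss"):
        assert col in frame.columns
        assert np.isfinite(frame[col]).all()
    assert len(frame) <= history.best_epoch + tiny_cfg.patience + 1
    assert history.best_val == pytest.approx(frame["val_loss"].min())
    # the combination identity holds for every logged epoch
    np.testing.assert_allclose(
        frame["l_gtv"],
        frame["l_dice"] + tiny_cfg.focal_scale_beta * frame["l_focal"],
        rtol=1e-5,
    )


def test_training_is_seeded_deterministic(tiny_cfg, tiny_cohort):
    tr, va = split_cohort(tiny_cohort, 3, seed=1)
    runs = []
    for _ in range(2):
        model = MultiTaskNet(tiny_cfg, np.random.default_rng(tiny_cfg.seed))
        _, hist = train(model, tr, va, tiny_cfg)
        runs.append(hist.frame)
    np.testing.assert_array_equal(runs[0]["l_joint"], runs[1]["l_joint"])
    np.testing.assert_array_equal(runs[0]["val_loss"], runs[1]["val_loss"])


def test_checkpoint_round_trip_identical_predictions(trained, tiny_cfg,
                                                     tmp_path):
    model, state, _, _, va = trained
    np.savez(tmp_path / "ckpt.npz", **state)
    clone = MultiTaskNet(tiny_cfg, np.random.default_rng(999))  # fresh init
    clone.load(tmp_path / "ckpt.npz")
    clone.eval()
    model.eval()
    patient = va[0]
    preds_a, call_a = predict_patient(model, patient, tiny_cfg)
    preds_b, call_b = predict_patient(clone, patient, tiny_cfg)
    for a, b in zip(preds_a, preds_b):
        np.testing.assert_array_equal(a.seg_prob, b.seg_prob)
        assert a.mutation_prob == b.mutation_prob
    assert call_a.label == call_b.label and call_a.mean_prob == call_b.mean_prob


def test_patient_call_uses_only_its_own_slices(trained, tiny_cfg):
    model, _, _, _, va = trained
    patient = va[0]
    _, alone = predict_patient(model, patient, tiny_cfg)
    _, again = predict_patient(model, patient, tiny_cfg)
    assert alone.mean_prob == again.mean_prob  # no cross-call state


def test_prediction_masks_are_thresholded_probabilities(trained, tiny_cfg):
    model, _, _, _, va = trained
    preds, _ = predict_patient(model, va[0], tiny_cfg)
    for p in preds:
        assert ((p.seg_prob > tiny_cfg.seg_threshold) == p.seg_mask.astype(bool)).all()
        assert 0.0 <= p.mutation_prob <= 1.0
        assert (p.seg_prob >= 0).all() and (p.seg_prob <= 1).all()


def test_run_directory_artifacts(tiny_cfg, tiny_cohort, tmp_path):
    tr, va = split_cohort(tiny_cohort, 3, seed=1)
    cfg = type(tiny_cfg)(**{**tiny_cfg.to_dict(), "max_epochs": 1})
    model = MultiTaskNet(cfg, np.random.default_rng(cfg.seed))
    train(model, tr, va, cfg, run_dir=tmp_path / "run")
    for name in ("config.yaml", "history.csv", "checkpoint.npz", "train.log"):
        assert (tmp_path / "run" / name).exists()


def test_multitask_branch_helps_or_matches_classification():
    """With the genotype signal confined to lesions, the shared encoder
    trained WITH the segmentation branch should classify at least as well
    (median over seeds) as the same encoder+classifier without it."""
    from msanet import (NetworkConfig, PhantomParams, SingleTaskNet,
                        generate_cohort, validate_config)
    from msanet.metrics import classification_report
    from msanet.backbone import as_batch
    from msanet.nn import softmax, Tensor

    params = PhantomParams(image_size=48, seed=17)
    cohort = generate_cohort(40, params)
    tr, va, te = cohort[:24], cohort[24:28], cohort[28:]

    def accuracy(model, cfg):
        preds, truths = [], []
        for case in te:
            _, call = predict_patient(model, case, cfg)
            preds.append(call.label)
            truths.append(case.genotype)
        return classification_report(preds, truths)[0]

    deltas = []
    for seed in (0, 1, 2):
        cfg = validate_config(NetworkConfig(
            input_size=48, stage_channels=[6, 12, 24, 48, 48],
            patch_grid=3, pool_kernel=3, mlp_hidden=16, batch_size=8,
            max_epochs=10, seed=seed))
        multi = MultiTaskNet(cfg, np.random.default_rng(seed))
        train(multi, tr, va, cfg)
        single = SingleTaskNet(cfg, np.random.default_rng(seed))
        train(single, tr, va, cfg)
        # the single-task model has no mask to rank slices by: average all
        single_preds, single_truths = [], []
        for case in te:
            images = np.stack([zscore(s.image) for s in case.slices])
            single.eval()
            _, logits = single(as_batch(images))
            probs = softmax(Tensor(logits.data), axis=-1).data[:, 1]
            single_preds.append(int(probs.mean() > cfg.class_threshold))
            single_truths.append(case.genotype)
        acc_single = classification_report(single_preds, single_truths)[0]
        deltas.append(accuracy(multi, cfg) - acc_single)
    assert np.median(deltas) >= 0.0
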