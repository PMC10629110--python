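# msanet

Multi-task deep learning for lesion-bearing 2-D MR-like slices:
simultaneous **gross-tumor-volume (GTV) segmentation** and **binary
genotype classification** (e.g. EGFR mutant vs wild-type inferred from
contrast-enhanced imaging of brain metastases), with patient-level
post-processing.

## Who this is for

Researchers in radiogenomics / medical image analysis who want a fully
inspectable, dependency-light reference implementation of a multi-task
segmentation + classification network — including its composite loss,
metric suite and slice-to-patient aggregation — that runs end-to-end on
synthetic phantom cohorts with no clinical data and no GPU.

## The model

A shared **multi-scale attention (MSA) encoder** (5 levels, stride-2
downsampling) feeds two heads:

* a U-shaped **decoder** (stride-2 transposed convolutions + skip
  fusion + 1x1 conv + sigmoid) producing a full-resolution foreground
  probability map;
* a **transformer classifier**: the deepest map (24x24 for 384-pixel
  inputs) is split into 16 patches, each flattened to a 36-token
  sequence and passed through a shared multi-head self-attention block
  (`Attention(Q,K,V) = softmax(QK^T / sqrt(d)) V`), then pooled,
  flattened and reduced by an MLP to softmax genotype probabilities.

Each MSA module builds a convolutional attention map from a local 3x3
convolution plus three depth-wise strip-convolution branches
(k in {5,7,11}) over a shared depth-wise 5x5, mixes with a 1x1
convolution, and reweights the input element-wise:

    Att = Conv1x1(Conv3x3(F) + sum_i Branch_i(DWConv(F))),  Out = Att * F

Training minimizes the uncertainty-weighted joint loss

    L_joint = L_GTV/(2 sigma_GTV^2) + L_EGFR/(2 sigma_EGFR^2)
              + log(sigma_GTV sigma_EGFR)

with `L_GTV = L_Dice + (1/25000) * L_Focal` (pixel-summed focal loss,
alpha = 0.8, gamma = 2), `L_EGFR` the cross-entropy, and learnable
sigmas initialized at 1.  Optimization is Adam at 3e-4 with patience-20
early stopping on the validation joint loss.

At inference, per-slice mutation probabilities become one patient call:
slices are ranked by predicted lesion area, the top half averaged, and
the patient is called mutant iff that mean exceeds 0.5.

The network runs on a compact numpy reverse-mode autodiff engine that
ships with the package (`msanet.nn`) — no deep-learning framework
required.

## Worked example

```python
import numpy as np
from msanet import (PhantomParams, generate_cohort, phantom_config,
                    MultiTaskNet, split_cohort)
from msanet.train import train, evaluate_cohort

cohort = generate_cohort(100, PhantomParams(seed=0))     # 96x96 phantoms
test_set = cohort[80:]
train_set, val_set = split_cohort(cohort[:80], 20, seed=0)

cfg = phantom_config(seed=0, max_epochs=16)
model = MultiTaskNet(cfg, np.random.default_rng(cfg.seed))
train(model, train_set, val_set, cfg)

report = evaluate_cohort(model, test_set, cfg)
print(report.seg)   # {'dice': 0.9625, 'hd95': 4.44, 'pixel_precision': 0.9635, ...}
print(report.cls)   # {'accuracy': 0.85, 'precision': 1.0, 'recall': 0.75, ...}
```

On the 20 held-out phantom patients this run prints a slice-level mean
Dice of 0.9625 (overlap between predicted and true lesion masks), a
mean HD95 of 4.4 mm (95th-percentile boundary distance), and a
patient-level genotyping accuracy of 0.85 with precision 1.0 (17/20
patients called correctly, no false mutant calls) — the phantom's
genotype signal is a rim-enhancement pattern confined to the lesions,
so these numbers show the pipeline recovers a lesion-confined class
signal end to end.  Training takes roughly ten minutes on one CPU.

The same pipeline is scriptable from the shell:

```bash
msanet simulate --n 100 --seed 0 --out data/
msanet train    --manifest data/manifest.yaml --out runs/demo --seed 0
msanet predict  --run runs/demo --manifest data/manifest.yaml --out preds/
msanet evaluate --run runs/demo --manifest data/manifest.yaml --out eval/
```

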