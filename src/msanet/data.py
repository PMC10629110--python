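"""Core domain types: slices, patients, predictions and evaluation reports.

Conventions used throughout the package:

* images are rank-2 float arrays indexed (row, col), origin top-left;
* masks are rank-2 ``{0,1}`` integer arrays of identical shape;
* genotype is binary with 1 = mutant (the positive class of every
  classification metric) and 0 = wild-type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SliceSample", "PatientCase", "SlicePrediction", "EvalReport"]


@dataclass
class SliceSample:
    """One 2-D slice with its lesion mask — the training atom."""

    image: np.ndarray
    mask: np.ndarray
    patient_id: str
    genotype: int
    slice_index: int

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        if self.image.ndim != 2:
            raise ValueError(f"image must be rank-2, got shape {self.image.shape}")
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image/mask shape mismatch: {self.image.shape} vs {self.mask.shape}"
            )
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be in {{0,1}}, got {vals[:8]}")
        if self.genotype not in (0, 1):
            raise ValueError(f"genotype must be 0 or 1, got {self.genotype}")
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")


@dataclass
class PatientCase:
    """An ordered slice stack sharing one genotype — the unit of prediction."""

    patient_id: str
    slices: list[SliceSample]
    genotype: int

    def __post_init__(self):
        if not self.slices:
            raise ValueError(f"patient {self.patient_id} has no slices")
        idx = [s.slice_index for s in self.slices]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("slice_index must be strictly increasing")
        for s in self.slices:
            if s.patient_id != self.patient_id:
                raise ValueError("slice patient_id mismatch")
            if s.genotype != self.genotype:
                raise ValueError("slice genotype mismatch")

    def __len__(self):
        return len(self.slices)


@dataclass
class SlicePrediction:
    """Per-slice network output: probability map, binary mask, class score."""

    seg_prob: np.ndarray
    seg_mask: np.ndarray
    mutation_prob: float
    slice_index: int

    def __post_init__(self):
        if not (0.0 <= self.mutation_prob <= 1.0):
            raise ValueError(f"mutation_prob outside [0,1]: {self.mutation_prob}")
        if self.seg_prob.shape != self.seg_mask.shape:
            raise ValueError("seg_prob/seg_mask shape mismatch")


@dataclass
class EvalReport:
    """Slice-level segmentation and patient-level classification metrics."""

    seg: dict = field(default_factory=dict)   # dice, hd95, pixel_precision, pixel_recall
    cls: dict = field(default_factory=dict)   # accuracy, precision, recall, f1
    per_patient: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        rows = [("seg", k, v) for k, v in self.seg.items()]
        rows += [("cls", k, v) for k, v in self.cls.items()]
        return pd.DataFrame(rows, columns=["task", "metric", "value"])

    def save(self, directory):
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(d / "metrics.csv", index=False)
        self.per_patient.to_csv(d / "per_patient.csv", index=False)
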