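"""Slice-to-patient post-processing.

A 2-D network scores every slice independently, but the clinical call is
per patient.  Slices near the top or bottom of a lesion carry little
tumor, so their class scores are noisy.  The aggregation rule therefore:

1. computes the predicted-lesion area of every slice,
2. ranks slices by area, descending (ties broken by ascending
   slice_index, making the rule deterministic and permutation-invariant),
3. keeps the top half — ceil(n/2) slices, so a single-slice patient is
   still callable,
4. averages their mutation probabilities, and
5. calls the patient mutant iff that mean STRICTLY exceeds the
   threshold (default 0.5; ties go to wild-type).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .data import SlicePrediction

__all__ = ["SliceEvidence", "PatientCall", "slice_area", "aggregate_patient",
           "calls_to_frame"]


@dataclass
class SliceEvidence:
    """What one slice contributes to the patient call."""

    slice_index: int
    area: int
    mutation_prob: float

    def __post_init__(self):
        if self.area < 0:
            raise ValueError("area must be >= 0")
        if not (0.0 <= self.mutation_prob <= 1.0):
            raise ValueError("mutation_prob must lie in [0, 1]")

    @classmethod
    def from_prediction(cls, pred: SlicePrediction) -> "SliceEvidence":
        return cls(slice_index=pred.slice_index,
                   area=slice_area(pred.seg_mask),
                   mutation_prob=pred.mutation_prob)


@dataclass
class PatientCall:
    patient_id: str
    selected_slices: list[int]
    mean_prob: float
    label: int


def slice_area(mask) -> int:
    """Foreground pixel count of a binary mask."""
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"mask must be binary, got values {vals[:8]}")
    return int(mask.sum())


def aggregate_patient(evidence: list[SliceEvidence], threshold: float = 0.5,
                      patient_id: str = "") -> PatientCall:
    """Top-area-half mean-probability rule (see module docstring)."""
    if not evidence:
        raise ValueError("cannot aggregate an empty evidence list")
    ranked = sorted(evidence, key=lambda e: (-e.area, e.slice_index))
    n_keep = ceil(len(ranked) / 2)
    kept = ranked[:n_keep]
    mean_prob = float(np.mean([e.mutation_prob for e in kept]))
    return PatientCall(
        patient_id=patient_id,
        selected_slices=[e.slice_index for e in kept],
        mean_prob=mean_prob,
        label=int(mean_prob > threshold),
    )


def calls_to_frame(calls: list[PatientCall],
                   n_slices: dict[str, int] | None = None) -> pd.DataFrame:
    rows = [
        {
            "patient_id": c.patient_id,
            "n_slices": None if n_slices is None else n_slices.get(c.patient_id),
            "n_selected": len(c.selected_slices),
            "mean_prob": c.mean_prob,
            "label": c.label,
        }
        for c in calls
    ]
    return pd.DataFrame(rows)
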