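"""Dataset readers/writers and the manifest format.

A cohort on disk is one directory with, per patient, an image volume and
a mask volume in NIfTI (slices along the LAST axis), plus ``labels.csv``
(patient_id, genotype) and a YAML manifest:

    format_version: 1
    records:
      - {patient_id: P0000, image: P0000_image.nii, mask: P0000_mask.nii,
         genotype: 1}

Slices may alternatively be stored as 16-bit grayscale PNG rasters (one
file per slice, masks as 8-bit {0,255} PNGs); 16-bit storage quantizes
intensities to the per-slice min/max range in 65535 steps, which is
idempotent: re-saving a loaded cohort reproduces the files bit-for-bit.

``load_dataset`` applies the lesion-slice rule: slices whose mask is
empty are dropped, so assembled datasets contain only lesion-bearing
slices.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .data import PatientCase, SliceSample
from .train import zscore

__all__ = ["save_cohort", "load_dataset", "read_manifest", "FORMAT_VERSION"]

FORMAT_VERSION = 1


def _write_nifti(path: Path, volume: np.ndarray):
    nib.save(nib.Nifti1Image(volume, affine=np.eye(4)), str(path))


def _read_nifti(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def save_cohort(cohort: list[PatientCase], out_dir, fmt: str = "nifti") -> Path:
    """Write a cohort; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for case in cohort:
        if fmt == "nifti":
            img = np.stack([s.image for s in case.slices], axis=-1).astype(np.float32)
            msk = np.stack([s.mask for s in case.slices], axis=-1).astype(np.uint8)
            ipath, mpath = f"{case.patient_id}_image.nii", f"{case.patient_id}_mask.nii"
            _write_nifti(out / ipath, img)
            _write_nifti(out / mpath, msk)
        elif fmt == "png":
            idir, mdir = out / f"{case.patient_id}_image", out / f"{case.patient_id}_mask"
            idir.mkdir(exist_ok=True)
            mdir.mkdir(exist_ok=True)
            for s in case.slices:
                img = np.asarray(s.image, dtype=np.float64)
                lo, hi = float(img.min()), float(img.max())
                scale = (hi - lo) / 65535.0 or 1.0
                q = np.round((img - lo) / scale).astype(np.uint16)
                Image.fromarray(q).save(idir / f"{s.slice_index:04d}.png")
                Image.fromarray((s.mask * 255).astype(np.uint8)).save(
                    mdir / f"{s.slice_index:04d}.png"
                )
            ipath, mpath = idir.name, mdir.name
        else:
            raise ValueError(f"unknown format {fmt!r}")
        records.append({"patient_id": case.patient_id, "image": ipath,
                        "mask": mpath, "genotype": int(case.genotype)})
    pd.DataFrame(records)[["patient_id", "genotype"]].to_csv(
        out / "labels.csv", index=False
    )
    manifest = out / "manifest.yaml"
    manifest.write_text(yaml.safe_dump(
        {"format_version": FORMAT_VERSION, "format": fmt, "records": records},
        sort_keys=False,
    ))
    return manifest


def read_manifest(manifest_path) -> dict:
    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    if manifest.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported manifest version {manifest.get('format_version')}")
    root = manifest_path.parent
    for rec in manifest["records"]:
        if rec["genotype"] not in (0, 1):
            raise ValueError(f"genotype must be 0/1 for {rec['patient_id']}")
        for key in ("image", "mask"):
            if not (root / rec[key]).exists():
                raise FileNotFoundError(root / rec[key])
    ids = [r["patient_id"] for r in manifest["records"]]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient_id in manifest")
    return manifest


def _binarize_mask(mask: np.ndarray, where: str) -> np.ndarray:
    vals = np.unique(mask)
    if np.isin(vals, (0, 1)).all():
        return mask.astype(np.uint8)
    if np.isin(vals, (0, 255)).all():  # common raster convention
        return (mask > 0).astype(np.uint8)
    raise ValueError(f"non-binary mask in {where}: values {vals[:8]}")


def _load_patient_arrays(root: Path, rec: dict, fmt: str):
    if fmt == "nifti":
        img = _read_nifti(root / rec["image"]).astype(np.float32)
        msk = np.asarray(_read_nifti(root / rec["mask"]))
        if img.shape != msk.shape:
            raise ValueError(f"image/mask geometry mismatch for {rec['patient_id']}")
        n = img.shape[-1]
        return [(i, img[..., i], msk[..., i]) for i in range(n)]
    # png: one file per slice, slice index from the file name
    out = []
    ifiles = sorted((root / rec["image"]).glob("*.png"))
    for ifile in ifiles:
        idx = int(ifile.stem)
        img = np.asarray(Image.open(ifile), dtype=np.float32)
        msk = np.asarray(Image.open(root / rec["mask"] / ifile.name))
        if img.shape != msk.shape:
            raise ValueError(f"image/mask geometry mismatch for {rec['patient_id']}")
        out.append((idx, img, msk))
    return out


def load_dataset(manifest_path, normalize: bool = True,
                 drop_empty: bool = True) -> list[PatientCase]:
    """Assemble PatientCases from a manifest, in manifest order.

    Empty-mask slices are dropped (``drop_empty``) and images z-scored
    per slice (``normalize``) unless disabled.
    """
    manifest = read_manifest(manifest_path)
    root = Path(manifest_path).parent
    fmt = manifest.get("format", "nifti")
    cases = []
    for rec in manifest["records"]:
        slices = []
        for idx, img, msk in _load_patient_arrays(root, rec, fmt):
            msk = _binarize_mask(msk, where=f"{rec['patient_id']}[{idx}]")
            if drop_empty and msk.sum() == 0:
                continue
            slices.append(SliceSample(
                image=zscore(img) if normalize else img,
                mask=msk, patient_id=rec["patient_id"],
                genotype=int(rec["genotype"]), slice_index=idx,
            ))
        if not slices:
            raise ValueError(f"patient {rec['patient_id']} has no lesion-bearing slices")
        cases.append(PatientCase(patient_id=rec["patient_id"], slices=slices,
                                 genotype=int(rec["genotype"])))
    return cases
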