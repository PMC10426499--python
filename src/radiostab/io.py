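"""Cohort persistence: NIfTI image/mask pairs plus labels.csv."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from radiostab.core import VolumeWithMask


def _affine(spacing) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def save_cohort(cohort, out_dir: str | Path, subject_ids: list[str] | None = None) -> None:
    """Write ``img_<id>.nii`` / ``mask_<id>.nii`` pairs and ``labels.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = list(cohort)
    if subject_ids is None:
        subject_ids = [f"s{i:03d}" for i in range(len(cohort))]
    rows = []
    for sid, (v, label) in zip(subject_ids, cohort):
        aff = _affine(v.spacing)
        nib.save(nib.Nifti1Image(v.intensities.astype(np.float32), aff), out / f"img_{sid}.nii")
        nib.save(nib.Nifti1Image(v.mask.astype(np.uint8), aff), out / f"mask_{sid}.nii")
        rows.append({"subject_id": sid, "label": int(label)})
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)


def load_cohort(in_dir: str | Path) -> tuple[list[tuple[VolumeWithMask, int]], list[str]]:
    """Read a cohort written by :func:`save_cohort`."""
    src = Path(in_dir)
    labels = pd.read_csv(src / "labels.csv").set_index("subject_id")["label"]
    cohort = []
    ids = []
    for sid, label in labels.items():
        img = nib.load(src / f"img_{sid}.nii")
        msk = nib.load(src / f"mask_{sid}.nii")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        v = VolumeWithMask(
            np.asarray(img.dataobj, dtype=np.float64),
            spacing,
            np.asarray(msk.dataobj) > 0,
        )
        cohort.append((v, int(label)))
        ids.append(str(sid))
    return cohort, ids
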