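"""Reading and writing exams on disk.

Exam-directory layout
---------------------
::

    <exam_dir>/
        metadata.json          # exam_id, pixel_spacing (mm), labels (mmHg / WU)
        2CH.nii.gz             # one NIfTI per view, (H, W, P) with P phases
        4CH.nii.gz  RVLA.nii.gz  SAX.nii.gz
        masks/2CH_LV.nii.gz    # optional binary chamber masks, same layout

A *store* is a directory of exam directories plus an optional ``labels.csv``
(columns exam_id, mPAP, PAWP, PVR).  DICOM series are read one directory
per view, frames ordered by InstanceNumber.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exam import TARGETS, VIEW_CHAMBERS, VIEWS, ChamberMaskSet, CineExam, RawCineSeries

__all__ = ["write_exam", "read_exam", "read_nifti_series", "read_dicom_series",
           "write_store", "iter_store", "store_labels"]


def _nifti_affine(spacing: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = spacing
    return aff


def write_exam(exam: CineExam, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    spacing = None
    for view in VIEWS:
        s = exam.series[view]
        spacing = s.pixel_spacing
        # (P, H, W) -> (H, W, P) on disk, phases along the last axis
        img = nib.Nifti1Image(np.transpose(s.frames, (1, 2, 0)),
                              _nifti_affine(spacing))
        nib.save(img, path / f"{view}.nii.gz")
    if exam.masks is not None:
        (path / "masks").mkdir(exist_ok=True)
        for view, chambers in exam.masks.masks.items():
            for ch, m in chambers.items():
                arr = np.transpose(m, (1, 2, 0)) if m.ndim == 3 else m
                img = nib.Nifti1Image(arr.astype(np.uint8), _nifti_affine(spacing))
                nib.save(img, path / "masks" / f"{view}_{ch}.nii.gz")
    meta = {
        "exam_id": exam.exam_id,
        "pixel_spacing": spacing,
        "labels": exam.labels,
        "masks_per_frame": bool(exam.masks.per_frame) if exam.masks else None,
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=1))


def read_nifti_series(path, view_id: str, pixel_spacing: float | None = None
                      ) -> RawCineSeries:
    img = nib.load(path)
    frames = np.transpose(np.asarray(img.dataobj, dtype=np.float32), (2, 0, 1))
    if pixel_spacing is None:
        pixel_spacing = float(img.affine[0, 0])
    return RawCineSeries(frames, abs(pixel_spacing), view_id)


def read_exam(path) -> CineExam:
    path = Path(path)
    meta = json.loads((path / "metadata.json").read_text())
    spacing = meta.get("pixel_spacing")
    series = {v: read_nifti_series(path / f"{v}.nii.gz", v, spacing) for v in VIEWS}
    masks = None
    mask_dir = path / "masks"
    if mask_dir.is_dir():
        per_frame = bool(meta.get("masks_per_frame", True))
        collected: dict[str, dict[str, np.ndarray]] = {}
        for view in VIEWS:
            for ch in VIEW_CHAMBERS[view]:
                f = mask_dir / f"{view}_{ch}.nii.gz"
                if f.exists():
                    arr = np.asarray(nib.load(f).dataobj).astype(np.uint8)
                    if arr.ndim == 3:
                        arr = np.transpose(arr, (2, 0, 1))
                    collected.setdefault(view, {})[ch] = arr
        if collected:
            masks = ChamberMaskSet(collected, per_frame=per_frame)
    return CineExam(series=series, labels=meta.get("labels"), masks=masks,
                    exam_id=meta.get("exam_id", path.name))


def read_dicom_series(directory, view_id: str) -> RawCineSeries:
    """Read one cine series from a directory of single-frame DICOM files."""
    import pydicom

    directory = Path(directory)
    files = sorted(directory.glob("*.dcm")) or sorted(
        p for p in directory.iterdir() if p.is_file())
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    datasets = [pydicom.dcmread(str(f)) for f in files]
    datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    frames = np.stack([d.pixel_array.astype(np.float32) for d in datasets])
    spacing = datasets[0].PixelSpacing
    if abs(float(spacing[0]) - float(spacing[1])) > 1e-6:
        raise ValueError("anisotropic pixel spacing is not supported")
    return RawCineSeries(frames, float(spacing[0]), view_id)


def write_store(exams, path) -> None:
    """Write exams into a store directory with a labels.csv."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for exam in exams:
        write_exam(exam, path / exam.exam_id)
        row = {"exam_id": exam.exam_id}
        row.update(exam.labels or {})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path / "labels.csv", index=False)


def iter_store(path):
    """Yield exams from a store directory, sorted by exam id."""
    path = Path(path)
    for sub in sorted(p for p in path.iterdir() if p.is_dir()):
        if (sub / "metadata.json").exists():
            yield read_exam(sub)


def store_labels(path) -> pd.DataFrame:
    path = Path(path)
    csv = path / "labels.csv"
    if csv.exists():
        return pd.read_csv(csv)
    rows = []
    for sub in sorted(p for p in path.iterdir() if p.is_dir()):
        meta_file = sub / "metadata.json"
        if meta_file.exists():
            meta = json.loads(meta_file.read_text())
            row = {"exam_id": meta.get("exam_id", sub.name)}
            row.update(meta.get("labels") or {})
            rows.append(row)
    return pd.DataFrame(rows, columns=["exam_id", *TARGETS])
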