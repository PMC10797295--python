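"""NIfTI volume / label-map I/O, affine co-registration, dataset manifests.

Conventions
-----------
* Arrays are stored ``(axial, coronal, sagittal)`` = (z, y, x), so the
  coarse 0.80 mm axis is axis 0 and the network patch ``(64, 160, 160)``
  reads directly off array shape.
* NIfTI-1, RAS+ world coordinates; the qform is preferred over the sform
  when both are set.
* Acquisition metadata (injected dose, clock times, weight, ...) travels in
  a JSON sidecar next to each volume, since NIfTI headers cannot carry it.
* A dataset on disk is ``root/<subject_id>/<timepoint dir>/`` containing
  ``ct.nii.gz``, ``pet.nii.gz``, ``labels.nii.gz`` and ``meta.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage


class DataError(Exception):
    """Malformed or inconsistent input data (CLI exit code 2)."""


#: fixed organ index table shared by every label map in the pipeline
ORGAN_TABLE: dict[int, str] = {
    0: "background",
    1: "heart",
    2: "lungs",
    3: "liver",
    4: "spleen",
    5: "kidneys",
    6: "tumor",
}
ORGAN_LABELS: dict[str, int] = {v: k for k, v in ORGAN_TABLE.items()}
FOREGROUND_ORGANS = tuple(n for n in ORGAN_TABLE.values() if n != "background")


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise DataError("affine must be an invertible 4x4 matrix")
    return affine


@dataclass
class ImageVolume:
    """A 3D scalar grid with voxel spacing, voxel-to-world affine, modality."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    modality: str  # "CT" or "PET"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DataError(f"non-3D payload: ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise DataError(f"spacing must be positive, got {self.spacing}")
        self.affine = _check_affine(self.affine)
        if self.modality not in ("CT", "PET"):
            raise DataError(f"unknown modality {self.modality!r}")

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class LabelMap:
    """Integer organ mask sharing an ImageVolume's grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    organ_table: dict[int, str] = field(default_factory=lambda: dict(ORGAN_TABLE))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DataError(f"non-3D payload: ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise DataError("label map must be integer-valued")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.affine = _check_affine(self.affine)
        present = set(np.unique(self.data).tolist())
        unknown = present - set(self.organ_table)
        if unknown:
            raise DataError(f"labels {sorted(unknown)} missing from organ table")

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def mask(self, organ: int | str) -> np.ndarray:
        label = ORGAN_LABELS[organ] if isinstance(organ, str) else int(organ)
        return self.data == label


@dataclass
class AcquisitionMeta:
    subject_id: str
    timepoint_h: float
    injected_dose_mbq: float
    isotope_half_life_h: float
    body_weight_g: float
    tumor_status: str = "healthy"  # or "tumor_bearing"
    isotope: str = "Cu-64"

    def __post_init__(self):
        if self.injected_dose_mbq <= 0:
            raise DataError("injected dose must be positive")
        if self.isotope_half_life_h <= 0:
            raise DataError("isotope half-life must be positive")
        if self.body_weight_g <= 0:
            raise DataError("body weight must be positive")
        if self.timepoint_h < 0:
            raise DataError("timepoint must be >= 0")
        if self.tumor_status not in ("healthy", "tumor_bearing"):
            raise DataError(f"bad tumor status {self.tumor_status!r}")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "AcquisitionMeta":
        return cls(**json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# NIfTI read / write
# --------------------------------------------------------------------------

def _affine_from_nifti(img) -> np.ndarray:
    hdr = img.header
    if int(hdr["qform_code"]) > 0:
        return img.get_qform()
    if int(hdr["sform_code"]) > 0:
        return img.get_sform()
    return img.affine


def read_volume(path, modality: str) -> ImageVolume:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DataError(f"non-3D payload in {path}: ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(data=data, spacing=spacing,
                       affine=_affine_from_nifti(img), modality=modality)


def write_volume(vol: ImageVolume, path) -> None:
    img = nib.Nifti1Image(vol.data, vol.affine)
    img.header.set_zooms(vol.spacing)
    img.header.set_data_dtype(vol.data.dtype)
    img.set_qform(vol.affine, code=1)
    img.set_sform(vol.affine, code=1)
    nib.save(img, str(path))


def read_labels(path, organ_table: dict[int, str] | None = None) -> LabelMap:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DataError(f"non-3D payload in {path}: ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelMap(data=data.astype(np.int16), spacing=spacing,
                    affine=_affine_from_nifti(img),
                    organ_table=dict(organ_table or ORGAN_TABLE))


def write_labels(labels: LabelMap, path) -> None:
    img = nib.Nifti1Image(labels.data.astype(np.int16), labels.affine)
    img.header.set_zooms(labels.spacing)
    img.header.set_data_dtype(np.int16)
    img.set_qform(labels.affine, code=1)
    img.set_sform(labels.affine, code=1)
    nib.save(img, str(path))


# --------------------------------------------------------------------------
# Affine co-registration
# --------------------------------------------------------------------------

def apply_affine_registration(moving, transform: np.ndarray, reference,
                              interpolation: str = "linear"):
    """Resample ``moving`` onto ``reference``'s grid under a world transform.

    ``transform`` is a 4x4 matrix mapping moving-space world coordinates to
    reference-space world coordinates (the forward registration transform,
    as exported by scanner workstations). Label maps must use nearest
    interpolation; images default to linear.
    """
    transform = np.asarray(transform, dtype=float)
    if transform.shape != (4, 4) or abs(np.linalg.det(transform)) < 1e-12:
        raise DataError("singular or non-4x4 registration transform")
    if interpolation not in ("linear", "nearest"):
        raise DataError(f"unknown interpolation {interpolation!r}")
    is_labels = isinstance(moving, LabelMap)
    if is_labels and interpolation != "nearest":
        raise DataError("label maps require nearest interpolation")

    # output voxel -> ref world -> moving world -> moving voxel
    m = (np.linalg.inv(moving.affine) @ np.linalg.inv(transform)
         @ reference.affine)
    order = 0 if interpolation == "nearest" else 1
    out = ndimage.affine_transform(
        moving.data.astype(np.float32 if not is_labels else moving.data.dtype),
        m[:3, :3], offset=m[:3, 3], output_shape=reference.data.shape,
        order=order, mode="constant", cval=0.0, prefilter=False)
    if is_labels:
        return LabelMap(data=out.astype(moving.data.dtype),
                        spacing=reference.spacing, affine=reference.affine,
                        organ_table=dict(moving.organ_table))
    return ImageVolume(data=out.astype(np.float32), spacing=reference.spacing,
                       affine=reference.affine, modality=moving.modality)


# --------------------------------------------------------------------------
# Dataset manifest
# --------------------------------------------------------------------------

MANIFEST_COLUMNS = ["subject_id", "timepoint_h", "ct_path", "pet_path",
                    "labels_path", "meta_path", "tumor_status", "fold"]


@dataclass
class DatasetManifest:
    """One row per (subject, timepoint) with file paths and fold assignment."""

    frame: pd.DataFrame

    def __post_init__(self):
        missing = set(MANIFEST_COLUMNS) - set(self.frame.columns)
        if missing:
            raise DataError(f"manifest missing columns {sorted(missing)}")
        dup = self.frame.duplicated(["subject_id", "timepoint_h"])
        if dup.any():
            rows = self.frame[dup][["subject_id", "timepoint_h"]]
            raise DataError(f"duplicate (subject, timepoint) rows:\n{rows}")

    def __len__(self):
        return len(self.frame)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.frame["subject_id"].unique())

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        frame = pd.read_csv(path)
        frame["fold"] = frame["fold"].astype("Int64")
        return cls(frame)

    def meta(self, row) -> AcquisitionMeta:
        return AcquisitionMeta.from_json(row["meta_path"])


def build_manifest(root) -> DatasetManifest:
    """Scan a dataset directory into a manifest, sorted by subject/timepoint."""
    root = Path(root)
    rows = []
    for subj_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for tp_dir in sorted(p for p in subj_dir.iterdir() if p.is_dir()):
            ct = tp_dir / "ct.nii.gz"
            pet = tp_dir / "pet.nii.gz"
            labels = tp_dir / "labels.nii.gz"
            meta_path = tp_dir / "meta.json"
            present = [p for p in (ct, pet, labels, meta_path) if p.exists()]
            if not present:
                continue
            missing = [p.name for p in (ct, pet, labels, meta_path)
                       if not p.exists()]
            if missing:
                raise DataError(f"incomplete case {tp_dir}: missing {missing}")
            meta = AcquisitionMeta.from_json(meta_path)
            rows.append({
                "subject_id": meta.subject_id,
                "timepoint_h": meta.timepoint_h,
                "ct_path": str(ct), "pet_path": str(pet),
                "labels_path": str(labels), "meta_path": str(meta_path),
                "tumor_status": meta.tumor_status, "fold": pd.NA,
            })
    frame = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    frame = frame.sort_values(["subject_id", "timepoint_h"],
                              ignore_index=True)
    frame["fold"] = frame["fold"].astype("Int64")
    return DatasetManifest(frame)


def assign_folds(manifest: DatasetManifest, k: int, seed: int,
                 split_by: str = "subject") -> DatasetManifest:
    """Randomly assign cross-validation folds of near-equal size.

    ``split_by="subject"`` (default) keeps all of a subject's timepoints in
    one fold, so no animal appears in both train and test;
    ``split_by="volume"`` splits individual volumes.
    """
    if k < 2:
        raise DataError("k must be >= 2")
    if len(manifest) == 0:
        raise DataError("cannot assign folds to an empty manifest")
    frame = manifest.frame.copy()
    rng = np.random.default_rng(seed)
    if split_by == "subject":
        units = np.array(manifest.subjects)
        key = "subject_id"
    elif split_by == "volume":
        units = frame.index.to_numpy()
        key = None
    else:
        raise DataError(f"split_by must be subject|volume, got {split_by!r}")
    if k > len(units):
        raise DataError(f"k={k} exceeds number of units ({len(units)})")
    order = rng.permutation(len(units))
    fold_of: dict = {}
    for fold, chunk in enumerate(np.array_split(units[order], k)):
        for u in chunk:
            fold_of[u] = fold
    if key:
        frame["fold"] = frame[key].map(fold_of).astype("Int64")
    else:
        frame["fold"] = pd.Series(frame.index.map(fold_of),
                                  index=frame.index, dtype="Int64")
    return DatasetManifest(frame)
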