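"""Data preparation: foreground cropping, intensity normalization, resampling.

The pipeline mirrors standard multi-scanner PET/CT harmonization:

1. crop to the CT foreground (largest connected component above a
   threshold) to drop the animal bed and distal structures,
2. normalize CT globally from a dataset *fingerprint* (clip at pooled
   foreground percentiles, then subtract pooled mean / divide pooled std),
3. Z-score each PET volume individually (its intensity scale depends on
   dose and decay, so no global statistic applies),
4. resample everything to a canonical voxel geometry, by default
   (0.80, 0.15, 0.15) mm for the (axial, coronal, sagittal) axes.

Normalization statistics are computed at native resolution, before
resampling. Images are interpolated linearly, label maps nearest-neighbor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume_io import DataError, ImageVolume, LabelMap

TARGET_SPACING: tuple[float, float, float] = (0.80, 0.15, 0.15)

#: default percentile of the in-volume histogram used as crop threshold
CROP_PERCENTILE = 60.0

#: CT clip percentiles applied to pooled foreground voxels before mean/std
CLIP_PERCENTILES: tuple[float, float] = (0.5, 99.5)


@dataclass
class CropBox:
    """Half-open per-axis voxel index ranges [lo, hi)."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self):
        self.lo = tuple(int(v) for v in self.lo)
        self.hi = tuple(int(v) for v in self.hi)
        if any(l < 0 or l >= h for l, h in zip(self.lo, self.hi)):
            raise DataError(f"invalid crop box {self.lo}..{self.hi}")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))


@dataclass
class DatasetFingerprint:
    """Global CT normalization statistics plus the canonical spacing."""

    ct_clip_low: float
    ct_clip_high: float
    ct_mean: float
    ct_std: float
    target_spacing: tuple[float, float, float] = TARGET_SPACING

    def __post_init__(self):
        if self.ct_std <= 0:
            raise DataError("degenerate fingerprint: ct_std must be > 0")
        if self.ct_clip_low >= self.ct_clip_high:
            raise DataError("degenerate fingerprint: clip_low >= clip_high")
        self.target_spacing = tuple(float(s) for s in self.target_spacing)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "DatasetFingerprint":
        d = json.loads(Path(path).read_text())
        d["target_spacing"] = tuple(d["target_spacing"])
        return cls(**d)


def compute_foreground_box(ct: ImageVolume, threshold: float | None = None,
                           percentile: float = CROP_PERCENTILE) -> CropBox:
    """Tightest box around the largest connected component above threshold.

    ``threshold`` defaults to the given percentile of the whole-volume
    intensity histogram, which is robust across scanners with different
    intensity calibrations (no absolute Hounsfield assumption).
    """
    data = ct.data
    if threshold is None:
        threshold = float(np.percentile(data, percentile))
    mask = data > threshold
    if not mask.any():
        raise DataError(f"empty foreground at threshold {threshold}")
    comp, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
        mask = comp == (int(np.argmax(sizes)) + 1)
    idx = np.nonzero(mask)
    lo = tuple(int(i.min()) for i in idx)
    hi = tuple(int(i.max()) + 1 for i in idx)
    return CropBox(lo=lo, hi=hi)


def crop(vol, box: CropBox):
    """Crop a volume or label map to a box, shifting the affine origin."""
    affine = vol.affine.copy()
    affine[:3, 3] += affine[:3, :3] @ np.asarray(box.lo, dtype=float)
    if isinstance(vol, LabelMap):
        return LabelMap(data=vol.data[box.slices], spacing=vol.spacing,
                        affine=affine, organ_table=dict(vol.organ_table))
    return ImageVolume(data=vol.data[box.slices], spacing=vol.spacing,
                       affine=affine, modality=vol.modality)


def fit_fingerprint(training_cts: list[ImageVolume], boxes: list[CropBox],
                    clip_percentiles: tuple[float, float] = CLIP_PERCENTILES,
                    target_spacing=TARGET_SPACING) -> DatasetFingerprint:
    """Pool foreground CT voxels over all training cases and fit statistics.

    Clip percentiles are taken over the pooled voxels first; the mean and
    std are then computed on the clipped pool.
    """
    if not training_cts or len(training_cts) != len(boxes):
        raise DataError("need equally many CT volumes and crop boxes")
    pooled = np.concatenate([ct.data[b.slices].ravel().astype(np.float64)
                             for ct, b in zip(training_cts, boxes)])
    lo, hi = np.percentile(pooled, clip_percentiles)
    clipped = np.clip(pooled, lo, hi)
    std = float(clipped.std())
    if std == 0.0:
        raise DataError("degenerate fingerprint: zero pooled variance")
    return DatasetFingerprint(ct_clip_low=float(lo), ct_clip_high=float(hi),
                              ct_mean=float(clipped.mean()), ct_std=std,
                              target_spacing=tuple(target_spacing))


def normalize_ct(ct: ImageVolume, fp: DatasetFingerprint) -> ImageVolume:
    data = np.clip(ct.data.astype(np.float32), fp.ct_clip_low, fp.ct_clip_high)
    data = (data - fp.ct_mean) / fp.ct_std
    return ImageVolume(data=data.astype(np.float32), spacing=ct.spacing,
                       affine=ct.affine, modality=ct.modality)


def normalize_pet(pet: ImageVolume) -> ImageVolume:
    """Per-volume Z-score (population std): output has mean 0, std 1."""
    data = pet.data.astype(np.float64)
    std = data.std()
    if std == 0.0:
        raise DataError("constant PET volume cannot be Z-scored")
    data = (data - data.mean()) / std
    return ImageVolume(data=data.astype(np.float32), spacing=pet.spacing,
                       affine=pet.affine, modality=pet.modality)


def resample(vol, target_spacing=TARGET_SPACING):
    """Resample to the target spacing, preserving world extent.

    Output shape is ``max(1, round(shape * spacing / target))`` per axis;
    linear interpolation for images, nearest for label maps.
    """
    target = tuple(float(s) for s in target_spacing)
    in_shape = np.asarray(vol.data.shape)
    in_spacing = np.asarray(vol.spacing)
    out_shape = np.maximum(1, np.round(in_shape * in_spacing / target)).astype(int)
    if tuple(out_shape) == tuple(in_shape) and np.allclose(in_spacing, target):
        out = vol.data.copy()
    else:
        factors = out_shape / in_shape
        is_labels = isinstance(vol, LabelMap)
        out = ndimage.zoom(
            vol.data if is_labels else vol.data.astype(np.float32),
            factors, order=0 if is_labels else 1, mode="nearest",
            grid_mode=True, prefilter=False)
        out = out[:out_shape[0], :out_shape[1], :out_shape[2]]
    affine = vol.affine.copy()
    affine[:3, :3] = affine[:3, :3] @ np.diag(in_shape / out_shape)
    if isinstance(vol, LabelMap):
        return LabelMap(data=out.astype(vol.data.dtype), spacing=target,
                        affine=affine, organ_table=dict(vol.organ_table))
    return ImageVolume(data=out.astype(np.float32), spacing=target,
                       affine=affine, modality=vol.modality)


def prepare_case(ct: ImageVolume, pet: ImageVolume, labels: LabelMap | None,
                 fp: DatasetFingerprint,
                 crop_percentile: float = CROP_PERCENTILE):
    """Crop -> normalize -> resample one co-registered CT/PET(/labels) case.

    All inputs must share one grid; outputs share one grid at the
    fingerprint's target spacing. Returns ``(ct', pet', labels')`` with
    ``labels'`` None when no label map is given.
    """
    if ct.data.shape != pet.data.shape or (
            labels is not None and labels.data.shape != ct.data.shape):
        raise DataError("case volumes are not on a common grid")
    box = compute_foreground_box(ct, percentile=crop_percentile)
    ct_c, pet_c = crop(ct, box), crop(pet, box)
    labels_c = crop(labels, box) if labels is not None else None
    ct_n = normalize_ct(ct_c, fp)
    pet_n = normalize_pet(pet_c)
    ct_r = resample(ct_n, fp.target_spacing)
    pet_r = resample(pet_n, fp.target_spacing)
    labels_r = (resample(labels_c, fp.target_spacing)
                if labels_c is not None else None)
    return ct_r, pet_r, labels_r
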