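"""Sliding-window inference over whole volumes.

Volumes larger than the network patch are tiled with 50%-overlapping
patches; overlapping class-score maps are blended with a Gaussian window
centered on each patch (predictions near patch borders see less context
and get less weight). Volumes smaller than the patch are symmetrically
zero-padded and cropped back afterwards. Ties in the per-voxel argmax
resolve to the lowest class index.
"""

from __future__ import annotations

import numpy as np

from .training import PreparedCase, TrainedModel
from .unet import UNet3D
from .volume_io import ORGAN_TABLE, DataError, ImageVolume, LabelMap


def _gaussian_window(patch: tuple[int, int, int]) -> np.ndarray:
    axes = []
    for p in patch:
        x = np.arange(p) - (p - 1) / 2.0
        axes.append(np.exp(-0.5 * (x / (p / 8.0)) ** 2))
    w = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    return (w / w.max()).astype(np.float32) + 1e-6


def _tile_starts(size: int, patch: int, overlap: float) -> list[int]:
    if size <= patch:
        return [0]
    step = max(1, int(round(patch * (1.0 - overlap))))
    starts = list(range(0, size - patch, step)) + [size - patch]
    return sorted(set(starts))


def sliding_window_scores(net: UNet3D, x: np.ndarray,
                          overlap: float = 0.5) -> np.ndarray:
    """Aggregate class scores over a full (C, D, H, W) volume."""
    patch = net.cfg.patch_size
    shape = np.asarray(x.shape[1:])
    psz = np.asarray(patch)
    pad = np.maximum(0, psz - shape)
    before = pad // 2
    after = pad - before
    if pad.any():
        x = np.pad(x, [(0, 0)] + [(int(b), int(a))
                                  for b, a in zip(before, after)])
    padded = np.asarray(x.shape[1:])
    scores = np.zeros((net.cfg.n_classes, *padded), dtype=np.float32)
    weight = np.zeros(padded, dtype=np.float32)
    win = _gaussian_window(patch)
    for z0 in _tile_starts(padded[0], patch[0], overlap):
        for y0 in _tile_starts(padded[1], patch[1], overlap):
            for x0 in _tile_starts(padded[2], patch[2], overlap):
                sl = (slice(z0, z0 + patch[0]), slice(y0, y0 + patch[1]),
                      slice(x0, x0 + patch[2]))
                logits = net.forward(np.ascontiguousarray(
                    x[(slice(None),) + sl]))
                scores[(slice(None),) + sl] += logits * win
                weight[sl] += win
    scores /= weight
    crop = tuple(slice(int(b), int(b + s))
                 for b, s in zip(before, shape))
    return scores[(slice(None),) + crop]


def predict(model: TrainedModel, ct: ImageVolume | None,
            pet: ImageVolume | None, overlap: float = 0.5) -> LabelMap:
    """Segment one preprocessed case; returns labels on the input grid.

    The model's subset spec decides which modalities are consumed; both
    arguments must still be co-registered when both are given. Class
    channels map back to the original organ label ids, so subtracted-organ
    models simply never emit that organ.
    """
    modality = model.subset.modality
    if modality in ("both", "ct_only") and ct is None:
        raise DataError("model requires a CT input")
    if modality in ("both", "pet_only") and pet is None:
        raise DataError("model requires a PET input")
    ref = ct if ct is not None else pet
    if ct is not None and pet is not None \
            and ct.data.shape != pet.data.shape:
        raise DataError("CT and PET are not on a common grid")
    if modality == "ct_only":
        x = ct.data[None]
    elif modality == "pet_only":
        x = pet.data[None]
    else:
        x = np.stack([ct.data, pet.data])
    scores = sliding_window_scores(model.net,
                                   np.ascontiguousarray(x, dtype=np.float32),
                                   overlap)
    pred = np.argmax(scores, axis=0)
    labels = np.asarray(model.classes, dtype=np.int16)[pred]
    return LabelMap(data=labels, spacing=ref.spacing, affine=ref.affine,
                    organ_table=dict(ORGAN_TABLE))


def predict_case(model: TrainedModel, case: PreparedCase,
                 overlap: float = 0.5) -> LabelMap:
    return predict(model, case.ct, case.pet, overlap)
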