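"""Grad-CAM saliency for the segmentation network.

For a dense-prediction network the "class score" is taken as the sum of
the target class's pre-argmax score map over the patch. Channel weights
are the spatial averages of the gradients of that score with respect to a
chosen convolutional layer's feature maps; the heatmap is the rectified
weighted sum of those maps, upsampled to the patch grid and normalized to
a maximum of 1. The default layer is the last decoder convolution before
the classification head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .training import TrainedModel
from .volume_io import ORGAN_LABELS, DataError


@dataclass
class SaliencyMap:
    heatmap: np.ndarray  # non-negative, max 1 when nonzero; patch grid
    organ: str
    layer: str


def grad_cam(model: TrainedModel, x: np.ndarray, organ: int | str,
             layer: str | None = None) -> SaliencyMap:
    """Heatmap of the regions driving one organ's segmentation score.

    ``x`` is a preprocessed input of shape (in_channels, *patch_size);
    smaller inputs are symmetrically zero-padded (and the heatmap cropped
    back).
    """
    net = model.net
    layer = layer or net.last_feature_layer
    if layer not in {name for name, _ in net.modules()}:
        raise DataError(f"layer {layer!r} not found")
    label = ORGAN_LABELS[organ] if isinstance(organ, str) else int(organ)
    if label not in model.classes:
        raise DataError(f"organ label {label} not in model's class list")
    class_idx = model.classes.index(label)
    organ_name = organ if isinstance(organ, str) else \
        {v: k for k, v in ORGAN_LABELS.items()}[label]

    patch = net.cfg.patch_size
    shape = np.asarray(x.shape[1:])
    psz = np.asarray(patch)
    if (shape > psz).any():
        raise DataError(f"input {tuple(shape)} exceeds patch {patch}")
    pad = psz - shape
    before = pad // 2
    if pad.any():
        x = np.pad(x, [(0, 0)] + [(int(b), int(p - b))
                                  for b, p in zip(before, pad)])

    logits = net.forward(np.ascontiguousarray(x, dtype=np.float32),
                         train=True, record=(layer,))
    acts = net.activation(layer)
    gscore = np.zeros_like(logits)
    gscore[class_idx] = 1.0  # d(sum of class score map)/d(logits)
    grads = net.backward(gscore, capture=layer)
    weights = grads.mean(axis=(1, 2, 3))
    cam = np.maximum(0.0, np.tensordot(weights, acts, axes=([0], [0])))
    zoom = psz / np.asarray(cam.shape)
    if not np.allclose(zoom, 1.0):
        cam = ndimage.zoom(cam, zoom, order=1, mode="nearest",
                           grid_mode=True, prefilter=False)
        cam = cam[:psz[0], :psz[1], :psz[2]]
    if pad.any():
        sl = tuple(slice(int(b), int(b + s)) for b, s in zip(before, shape))
        cam = cam[sl]
    m = cam.max()
    if m > 0:
        cam = cam / m
    return SaliencyMap(heatmap=cam.astype(np.float32), organ=organ_name,
                       layer=layer)
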