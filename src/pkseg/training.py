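"""Patch-based training of the segmentation network, with subset filtering.

Training follows the standard recipe for this architecture family: random
patches (half of them forced to contain foreground so sparse organs are
not drowned out by background), soft Dice + cross-entropy loss, SGD with
Nesterov momentum and polynomial learning-rate decay, and light
augmentation (axis flips, additive intensity jitter). One master seed fans
out to patch sampling, augmentation and weight initialization.

*Subset models* restrict the training data along one dimension — modality
(CT-only / PET-only input channels), imaging timepoint, tumor status — or
remove one organ from the training targets ("organ subtracted"): that
organ is relabelled to background and dropped from the model's class list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import DatasetFingerprint
from .volume_io import (ORGAN_LABELS, ORGAN_TABLE, AcquisitionMeta, DataError,
                        DatasetManifest, ImageVolume, LabelMap)
from .unet import NetConfig, UNet3D, build_network, dice_ce_loss
from . import nn


@dataclass
class SubsetSpec:
    """Training-data restriction; the default restricts nothing."""

    modality: str = "both"  # both | ct_only | pet_only
    timepoints: tuple[float, ...] | None = None
    tumor: str = "all"  # all | healthy_only | tumor_only
    organs_subtracted: tuple[str, ...] = ()

    def __post_init__(self):
        if self.modality not in ("both", "ct_only", "pet_only"):
            raise DataError(f"bad modality subset {self.modality!r}")
        if self.tumor not in ("all", "healthy_only", "tumor_only"):
            raise DataError(f"bad tumor subset {self.tumor!r}")
        if self.timepoints is not None:
            self.timepoints = tuple(float(t) for t in self.timepoints)
        self.organs_subtracted = tuple(self.organs_subtracted)
        for organ in self.organs_subtracted:
            if organ not in ORGAN_LABELS or organ == "background":
                raise DataError(f"unknown organ {organ!r}")

    @property
    def in_channels(self) -> int:
        return 1 if self.modality in ("ct_only", "pet_only") else 2

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "SubsetSpec":
        d = json.loads(text)
        if d.get("timepoints") is not None:
            d["timepoints"] = tuple(d["timepoints"])
        d["organs_subtracted"] = tuple(d.get("organs_subtracted", ()))
        return cls(**d)


@dataclass
class TrainConfig:
    epochs: int = 50
    patches_per_epoch: int = 10
    lr: float = 0.03
    momentum: float = 0.9
    lr_decay_power: float = 0.9
    fg_oversample: float = 0.5
    augment_flip: bool = True
    intensity_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise DataError("epochs must be >= 1")
        if not 0.0 <= self.fg_oversample <= 1.0:
            raise DataError("fg_oversample must be in [0, 1]")


@dataclass
class PreparedCase:
    """One preprocessed (ct', pet', labels') triple plus its metadata."""

    ct: ImageVolume
    pet: ImageVolume
    labels: LabelMap | None
    meta: AcquisitionMeta

    def channels(self, modality: str) -> np.ndarray:
        if modality == "ct_only":
            arrs = [self.ct.data]
        elif modality == "pet_only":
            arrs = [self.pet.data]
        else:
            arrs = [self.ct.data, self.pet.data]
        return np.stack([a.astype(np.float32) for a in arrs])


def filter_cases(cases: list[PreparedCase],
                 subset: SubsetSpec) -> list[PreparedCase]:
    out = []
    for c in cases:
        if subset.timepoints is not None and not any(
                abs(c.meta.timepoint_h - t) < 1e-9 for t in subset.timepoints):
            continue
        if subset.tumor == "healthy_only" and c.meta.tumor_status != "healthy":
            continue
        if subset.tumor == "tumor_only" and c.meta.tumor_status != "tumor_bearing":
            continue
        out.append(c)
    return out


def class_list(subset: SubsetSpec) -> list[int]:
    """Original organ labels kept as prediction targets, 0 first."""
    removed = {ORGAN_LABELS[o] for o in subset.organs_subtracted}
    return [l for l in sorted(ORGAN_TABLE) if l not in removed]


def remap_targets(labels: np.ndarray, classes: list[int]) -> np.ndarray:
    """Map original organ labels to contiguous class indices (dropped -> 0)."""
    lut = np.zeros(max(ORGAN_TABLE) + 1, dtype=np.int64)
    for idx, label in enumerate(classes):
        lut[label] = idx
    return lut[labels]


@dataclass
class TrainedModel:
    net: UNet3D
    net_cfg: NetConfig
    subset: SubsetSpec
    classes: list[int]  # original label ids, position = class channel
    fingerprint: DatasetFingerprint | None = None

    def save(self, path) -> None:
        path = Path(path)
        meta = {
            "net_cfg": {k: v for k, v in asdict(self.net_cfg).items()},
            "subset": asdict(self.subset),
            "classes": self.classes,
            "fingerprint": (asdict(self.fingerprint)
                            if self.fingerprint else None),
        }
        np.savez(path, __meta__=json.dumps(meta, default=list),
                 **self.net.state_dict())

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            state = {k: z[k] for k in z.files if k != "__meta__"}
        cfg_d = meta["net_cfg"]
        cfg_d["patch_size"] = tuple(cfg_d["patch_size"])
        if cfg_d["strides"] is not None:
            cfg_d["strides"] = tuple(tuple(s) for s in cfg_d["strides"])
        cfg = NetConfig(**cfg_d)
        subset = SubsetSpec(**{**meta["subset"], "timepoints":
                               tuple(meta["subset"]["timepoints"])
                               if meta["subset"]["timepoints"] else None,
                               "organs_subtracted":
                               tuple(meta["subset"]["organs_subtracted"])})
        net = build_network(cfg, seed=0)
        net.load_state_dict(state)
        fp = meta["fingerprint"]
        return cls(net=net, net_cfg=cfg, subset=subset,
                   classes=list(meta["classes"]),
                   fingerprint=DatasetFingerprint(**{
                       **fp, "target_spacing": tuple(fp["target_spacing"])})
                   if fp else None)


def _sample_patch(case: PreparedCase, subset: SubsetSpec, classes: list[int],
                  patch: tuple[int, int, int], cfg: TrainConfig,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    x = case.channels(subset.modality)
    t = remap_targets(case.labels.data.astype(np.int64), classes)
    shape = np.asarray(t.shape)
    psz = np.asarray(patch)
    pad = np.maximum(0, psz - shape)
    if pad.any():
        before = pad // 2
        after = pad - before
        wid = [(int(b), int(a)) for b, a in zip(before, after)]
        x = np.pad(x, [(0, 0)] + wid)
        t = np.pad(t, wid)
        shape = np.asarray(t.shape)
    if cfg.fg_oversample > 0 and rng.random() < cfg.fg_oversample:
        # class-balanced: center on a random voxel of a random present organ,
        # so sparse organs (spleen, kidneys) are seen as often as large ones
        present = np.unique(t)
        present = present[present > 0]
        if len(present):
            fg = np.argwhere(t == rng.choice(present))
            center = fg[rng.integers(len(fg))]
        else:
            center = shape // 2
        lo = np.clip(center - psz // 2, 0, shape - psz)
    else:
        lo = np.array([rng.integers(0, s - p + 1)
                       for s, p in zip(shape, psz)])
    sl = tuple(slice(int(l), int(l + p)) for l, p in zip(lo, psz))
    xp = x[(slice(None),) + sl].copy()
    tp = t[sl].copy()
    if cfg.augment_flip:
        for ax in range(3):
            if rng.random() < 0.5:
                xp = np.flip(xp, axis=ax + 1)
                tp = np.flip(tp, axis=ax)
    if cfg.intensity_jitter_sd > 0:
        xp = xp + rng.normal(0, cfg.intensity_jitter_sd,
                             xp.shape).astype(np.float32)
    return np.ascontiguousarray(xp, dtype=np.float32), \
        np.ascontiguousarray(tp)


def train_on_cases(cases: list[PreparedCase], net_cfg: NetConfig,
                   train_cfg: TrainConfig,
                   subset: SubsetSpec | None = None,
                   fingerprint: DatasetFingerprint | None = None
                   ) -> tuple[TrainedModel, pd.DataFrame]:
    """Train on preprocessed cases; returns the model and a per-epoch log."""
    subset = subset or SubsetSpec()
    cases = filter_cases(cases, subset)
    if not cases:
        raise DataError("training subset is empty after filtering")
    classes = class_list(subset)
    cfg_d = asdict(net_cfg)
    cfg_d["in_channels"] = subset.in_channels
    cfg_d["n_classes"] = len(classes)
    net_cfg = NetConfig(**cfg_d)
    rng = np.random.default_rng(train_cfg.seed)
    net = build_network(net_cfg, seed=int(rng.integers(2 ** 31 - 1)))
    opt = nn.SGD(net.params(), lr=train_cfg.lr, momentum=train_cfg.momentum)
    log = []
    for epoch in range(train_cfg.epochs):
        opt.lr = train_cfg.lr * (1.0 - epoch / train_cfg.epochs) \
            ** train_cfg.lr_decay_power
        losses = []
        for _ in range(train_cfg.patches_per_epoch):
            case = cases[rng.integers(len(cases))]
            x, t = _sample_patch(case, subset, classes, net_cfg.patch_size,
                                 train_cfg, rng)
            logits = net.forward(x, train=True)
            loss, g = dice_ce_loss(logits, t)
            opt.zero_grad()
            net.backward(g)
            opt.step()
            losses.append(loss)
        log.append({"epoch": epoch, "loss": float(np.mean(losses)),
                    "lr": opt.lr})
    model = TrainedModel(net=net, net_cfg=net_cfg, subset=subset,
                         classes=classes, fingerprint=fingerprint)
    return model, pd.DataFrame(log)


def load_prepared_manifest(manifest: DatasetManifest,
                           fp: DatasetFingerprint,
                           rows=None) -> list[PreparedCase]:
    """Read and preprocess manifest rows into training-ready cases."""
    from .preprocessing import prepare_case
    from .volume_io import read_labels, read_volume
    out = []
    frame = manifest.frame if rows is None else manifest.frame.iloc[rows]
    for _, row in frame.iterrows():
        ct = read_volume(row["ct_path"], "CT")
        pet = read_volume(row["pet_path"], "PET")
        labels = read_labels(row["labels_path"])
        meta = AcquisitionMeta.from_json(row["meta_path"])
        ct_p, pet_p, lab_p = prepare_case(ct, pet, labels, fp)
        out.append(PreparedCase(ct=ct_p, pet=pet_p, labels=lab_p, meta=meta))
    return out


def train(manifest: DatasetManifest, fold: int, net_cfg: NetConfig,
          train_cfg: TrainConfig, subset: SubsetSpec | None = None,
          fingerprint: DatasetFingerprint | None = None
          ) -> tuple[TrainedModel, pd.DataFrame]:
    """Train on every manifest row outside ``fold`` (the held-out test fold)."""
    if fingerprint is None:
        raise DataError("training requires a dataset fingerprint")
    folds = manifest.frame["fold"]
    if folds.isna().any():
        raise DataError("manifest has unassigned folds; run assign_folds")
    train_rows = np.flatnonzero((folds != fold).to_numpy())
    cases = load_prepared_manifest(manifest, fingerprint, train_rows)
    return train_on_cases(cases, net_cfg, train_cfg, subset, fingerprint)
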