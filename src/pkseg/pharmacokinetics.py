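"""Pharmacokinetic / dosimetry readouts from PET + organ masks + metadata.

Unit policy (centralized here): activity concentration in kBq/cc, doses in
MBq externally and kBq internally, body weight in grams, time in hours.
PET voxel values are taken to be decay-corrected-to-scan-time activity
concentration (the usual scanner convention); the *injected dose* is what
gets decay-corrected to the imaging timepoint, so

    %ID    = 100 * total organ activity / decay-corrected dose
    %ID/cc = %ID / organ volume          (organ-mean definition)
    SUV    = concentration / (decay-corrected dose / body weight)

``%ID/cc`` is reported as the organ mean; a per-voxel map is available via
:func:`pid_per_cc_map` but is not part of the default report.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .volume_io import (ORGAN_LABELS, AcquisitionMeta, DataError, ImageVolume,
                        LabelMap)

#: isotope half-lives in hours, keyed by isotope name
ISOTOPE_HALF_LIVES_H: dict[str, float] = {
    "Cu-64": 12.701,
    "F-18": 1.829,
    "Zr-89": 78.41,
    "Ga-68": 1.128,
}


@dataclass
class OrganPK:
    """All per-organ readouts for one volume at one timepoint."""

    organ: str
    volume_cc: float
    pid_per_cc: float
    pid: float
    suv_mean: float
    suv_max: float
    suv_min: float
    pet_mean: float
    pet_max: float
    pet_min: float
    pet_std: float


@dataclass
class PKTimeseries:
    organ: str
    timepoints_h: tuple[float, ...]
    pid_per_cc: tuple[float, ...]
    auc: float  # %ID/cc * h


def decay_correct_dose(meta: AcquisitionMeta) -> float:
    """Injected dose (MBq) decay-corrected to the imaging timepoint."""
    return meta.injected_dose_mbq * 2.0 ** (
        -meta.timepoint_h / meta.isotope_half_life_h)


def organ_pk(pet: ImageVolume, labels: LabelMap, organ: int | str,
             meta: AcquisitionMeta) -> OrganPK:
    """Compute the PK readouts of one organ from a PET volume and a mask."""
    if pet.data.shape != labels.data.shape:
        raise DataError("PET and labels are not on a common grid")
    mask = labels.mask(organ)
    n = int(mask.sum())
    if n == 0:
        name = organ if isinstance(organ, str) else labels.organ_table[organ]
        raise DataError(f"organ {name!r} absent from label map")
    name = (organ if isinstance(organ, str)
            else labels.organ_table[int(organ)])
    conc = pet.data[mask].astype(np.float64)  # kBq/cc
    vox_cc = labels.voxel_volume_cc
    volume_cc = n * vox_cc
    dose_kbq = decay_correct_dose(meta) * 1000.0
    total_activity_kbq = float(conc.sum()) * vox_cc
    pid = 100.0 * total_activity_kbq / dose_kbq
    suv_denom = dose_kbq / meta.body_weight_g
    return OrganPK(
        organ=name, volume_cc=volume_cc,
        pid_per_cc=pid / volume_cc, pid=pid,
        suv_mean=float(conc.mean()) / suv_denom,
        suv_max=float(conc.max()) / suv_denom,
        suv_min=float(conc.min()) / suv_denom,
        pet_mean=float(conc.mean()), pet_max=float(conc.max()),
        pet_min=float(conc.min()), pet_std=float(conc.std()),
    )


def pid_per_cc_map(pet: ImageVolume, meta: AcquisitionMeta) -> np.ndarray:
    """Voxelwise %ID/cc map (alternative to the organ-mean definition)."""
    dose_kbq = decay_correct_dose(meta) * 1000.0
    return 100.0 * pet.data.astype(np.float64) / dose_kbq


def auc_exposure(series) -> float:
    """Trapezoidal AUC over the observed timepoints only (no extrapolation)."""
    pts = sorted((float(t), float(v)) for t, v in series)
    if len(pts) < 2:
        raise DataError("AUC needs at least two timepoints")
    t = np.array([p[0] for p in pts])
    if np.any(np.diff(t) <= 0):
        raise DataError("duplicate timepoints in AUC series")
    v = np.array([p[1] for p in pts])
    return float(np.trapezoid(v, t))


def pk_report(cases: list[tuple[ImageVolume, LabelMap, AcquisitionMeta]]
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-organ PK table across a subject's timepoints, plus AUC exposures.

    Returns ``(per_timepoint, auc)`` data frames; the first holds one row
    per (timepoint, organ present), the second one row per organ with the
    trapezoidal %ID/cc exposure when >= 2 timepoints are available.
    """
    if not cases:
        raise DataError("empty case list")
    subjects = {m.subject_id for _, _, m in cases}
    if len(subjects) > 1:
        raise DataError(f"cases span multiple subjects: {sorted(subjects)}")
    tables = [tuple(sorted(lab.organ_table.items())) for _, lab, _ in cases]
    if len(set(tables)) > 1:
        raise DataError("inconsistent organ tables across timepoints")

    rows = []
    for pet, labels, meta in sorted(cases, key=lambda c: c[2].timepoint_h):
        present = set(np.unique(labels.data).tolist()) - {0}
        for label in sorted(present):
            pk = organ_pk(pet, labels, label, meta)
            rows.append({"subject_id": meta.subject_id,
                         "timepoint_h": meta.timepoint_h, **asdict(pk)})
    per_tp = pd.DataFrame(rows)
    if per_tp.empty:
        return per_tp, pd.DataFrame(
            columns=["subject_id", "organ", "auc_pid_per_cc_h"])

    auc_rows = []
    for organ, grp in per_tp.groupby("organ", sort=False):
        if len(grp) >= 2:
            auc_rows.append({
                "subject_id": grp["subject_id"].iloc[0], "organ": organ,
                "auc_pid_per_cc_h": auc_exposure(
                    list(zip(grp["timepoint_h"], grp["pid_per_cc"]))),
            })
    return per_tp, pd.DataFrame(auc_rows)


def fit_monoexponential_half_life(times_h, values) -> float:
    """Half-life from a log2-linear fit to a decaying timeseries.

    Used to recover the slow-phase clearance half-life from late-timepoint
    %ID/cc values, where the fast phase has already decayed away.
    """
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 2:
        raise DataError("need at least two points to fit a half-life")
    if np.any(v <= 0):
        raise DataError("half-life fit requires positive values")
    slope, _ = np.polyfit(t, np.log2(v), 1)
    if slope >= 0:
        raise DataError("series is not decaying; no half-life")
    return float(-1.0 / slope)
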