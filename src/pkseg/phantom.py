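"""Digital mouse phantoms: paired CT, PET, label maps and metadata.

The generator emulates the structure of a longitudinal preclinical
radiotracer study of a lipid-shelled agent in mice: a cohort of subjects
(about 35% healthy, 65% bearing an orthotopic mammary tumor), each imaged
at 1, 3.5, 6, 24 and 48 h post-injection of a Cu-64 labelled agent.

Geometry is a set of pairwise-disjoint ellipsoids (heart, two lung lobes,
liver, spleen, two kidneys, optional tumor) inside a rounded-cylinder
trunk, with an animal-bed slab below it. Default organ volumes are chosen
to match a ~22 g mouse (heart ~0.2 cc, lungs ~0.3 cc, liver ~1.4 cc,
spleen ~0.1 cc, kidneys ~0.12 cc each).

Tracer kinetics, expressed directly in %ID/cc:

* blood-pool organs (heart, lungs, kidneys, and a faint whole-body
  background) follow two-phase clearance
  ``f(t) = A_fast 2^(-t/T_fast) + A_slow 2^(-t/T_slow)`` with the long
  phase half-life drawn per subject from 5-11 h,
* accumulation organs (liver, spleen, tumor) follow
  ``f(t) = P (1 - 2^(-t/T_uptake)) 2^(-t/T_wash)``.

The PET image stores decay-corrected activity concentration in kBq/cc:
``conc = f(t)/100 * dose_decay_corrected``; it is spatially uniform within
each organ (plus optional Gaussian noise), which keeps every
pharmacokinetic readout available in closed form via
:func:`analytic_truth`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume_io import (ORGAN_LABELS, ORGAN_TABLE, AcquisitionMeta, DataError,
                        DatasetManifest, ImageVolume, LabelMap, build_manifest,
                        write_labels, write_volume)

DEFAULT_TIMEPOINTS: tuple[float, ...] = (1.0, 3.5, 6.0, 24.0, 48.0)
CU64_HALF_LIFE_H = 12.701


@dataclass
class Ellipsoid:
    """Center and radii as fractions of the half field-of-view per axis."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def in_mm(self, half_fov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return (np.asarray(self.center) * half_fov,
                np.asarray(self.radii) * half_fov)


@dataclass
class TwoPhase:
    """Biexponential clearance in %ID/cc."""

    a_fast: float
    t_half_fast_h: float
    a_slow: float
    t_half_slow_h: float

    def __call__(self, t: float) -> float:
        return (self.a_fast * 2.0 ** (-t / self.t_half_fast_h)
                + self.a_slow * 2.0 ** (-t / self.t_half_slow_h))


@dataclass
class Accumulation:
    """Uptake-then-washout kinetics in %ID/cc."""

    peak: float
    t_half_uptake_h: float
    t_half_wash_h: float

    def __call__(self, t: float) -> float:
        return (self.peak * (1.0 - 2.0 ** (-t / self.t_half_uptake_h))
                * 2.0 ** (-t / self.t_half_wash_h))


# fractions of the half field-of-view; z runs head (-) to tail (+)
_DEFAULT_GEOMETRY: dict[str, list[Ellipsoid]] = {
    "lungs": [Ellipsoid((-0.62, -0.18, -0.40), (0.16, 0.21, 0.19)),
              Ellipsoid((-0.62, -0.18, +0.40), (0.16, 0.21, 0.19))],
    "heart": [Ellipsoid((-0.28, 0.12, 0.0), (0.14, 0.24, 0.24))],
    "liver": [Ellipsoid((0.17, 0.02, -0.05), (0.20, 0.50, 0.54))],
    "spleen": [Ellipsoid((0.06, -0.24, 0.66), (0.13, 0.20, 0.155))],
    "kidneys": [Ellipsoid((0.54, 0.18, -0.44), (0.14, 0.215, 0.18)),
                Ellipsoid((0.54, 0.18, +0.44), (0.14, 0.215, 0.18))],
    "tumor": [Ellipsoid((0.76, 0.48, 0.12), (0.13, 0.26, 0.25))],
}

_DEFAULT_KINETICS: dict[str, TwoPhase | Accumulation] = {
    "heart": TwoPhase(15.0, 0.4, 6.0, 7.0),
    "lungs": TwoPhase(10.0, 0.4, 4.0, 7.0),
    "kidneys": TwoPhase(8.0, 0.5, 3.5, 7.0),
    "body": TwoPhase(1.0, 0.5, 0.5, 7.0),
    "liver": Accumulation(10.0, 3.0, 40.0),
    "spleen": Accumulation(8.0, 4.0, 50.0),
    "tumor": Accumulation(3.0, 8.0, 60.0),
}

_DEFAULT_CT: dict[str, float] = {
    "air": -1000.0, "body": 40.0, "bed": -300.0,
    "heart": 50.0, "lungs": -700.0, "liver": 80.0, "spleen": 70.0,
    "kidneys": 60.0, "tumor": 55.0,
}


@dataclass
class PhantomSpec:
    """Full description of one digital mouse at all timepoints."""

    shape: tuple[int, int, int] = (64, 96, 96)
    spacing: tuple[float, float, float] = (0.8, 0.3, 0.3)
    body_radii: tuple[float, float, float] = (0.97, 0.95, 0.93)
    geometry: dict[str, list[Ellipsoid]] = field(
        default_factory=lambda: copy.deepcopy(_DEFAULT_GEOMETRY))
    kinetics: dict[str, TwoPhase | Accumulation] = field(
        default_factory=lambda: copy.deepcopy(_DEFAULT_KINETICS))
    ct_values: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CT))
    injected_dose_mbq: float = 8.0
    isotope_half_life_h: float = CU64_HALF_LIFE_H
    body_weight_g: float = 22.0
    tumor_status: str = "tumor_bearing"
    subject_id: str = "m000"
    ct_noise_sd: float = 15.0
    pet_noise_sd_kbq_cc: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.tumor_status == "healthy":
            self.geometry.pop("tumor", None)
        for organs in self.geometry.values():
            for e in organs:
                if any(r <= 0 for r in e.radii):
                    raise DataError("ellipsoid radii must be positive")

    @property
    def half_fov_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.spacing) / 2.0

    @property
    def organs(self) -> list[str]:
        return [n for n in ORGAN_TABLE.values()
                if n in self.geometry]

    def pid_per_cc(self, organ: str, t: float) -> float:
        return float(self.kinetics[organ](t))


def _voxel_coords_mm(spec: PhantomSpec):
    """World offsets (mm) of voxel centers from the grid center, per axis."""
    axes = []
    for n, s in zip(spec.shape, spec.spacing):
        axes.append((np.arange(n) + 0.5) * s - n * s / 2.0)
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _decayed_dose_kbq(spec: PhantomSpec, t: float) -> float:
    return spec.injected_dose_mbq * 1000.0 * 2.0 ** (
        -t / spec.isotope_half_life_h)


def render_phantom(spec: PhantomSpec, t: float, rng=None):
    """Rasterize one (CT, PET, labels, meta) case at timepoint ``t`` hours.

    Deterministic for a given ``(spec.seed, t)`` unless an explicit ``rng``
    is supplied. Raises if two organ ellipsoids claim the same voxel.
    """
    if rng is None:
        rng = np.random.default_rng((spec.seed, int(round(t * 1000))))
    zz, yy, xx = _voxel_coords_mm(spec)
    half = spec.half_fov_mm

    labels = np.zeros(spec.shape, dtype=np.int16)
    for organ in spec.organs:
        lab = ORGAN_LABELS[organ]
        for ell in spec.geometry[organ]:
            c, r = ell.in_mm(half)
            inside = (((zz - c[0]) / r[0]) ** 2 + ((yy - c[1]) / r[1]) ** 2
                      + ((xx - c[2]) / r[2]) ** 2) <= 1.0
            clash = labels[inside]
            if (clash != 0).any() and not np.isin(
                    clash[clash != 0], lab).all():
                other = ORGAN_TABLE[int(clash[clash != 0][0])]
                raise DataError(f"overlapping organs: {organ} and {other}")
            labels[inside] = lab

    # rounded-cylinder trunk: steep z exponent gives a capped cylinder
    bz, by, bx = spec.body_radii * half
    body = ((zz / bz) ** 8 + (yy / by) ** 2 + (xx / bx) ** 2) <= 1.0
    bed = np.zeros(spec.shape, dtype=bool)
    bed[:, -max(1, spec.shape[1] // 48):, :] = True
    bed &= ~body

    ct = np.full(spec.shape, spec.ct_values["air"], dtype=np.float32)
    ct[bed] = spec.ct_values["bed"]
    ct[body] = spec.ct_values["body"]
    dose_kbq = _decayed_dose_kbq(spec, t)
    pet = np.zeros(spec.shape, dtype=np.float32)
    pet[body] = spec.kinetics["body"](t) / 100.0 * dose_kbq
    for organ in spec.organs:
        m = labels == ORGAN_LABELS[organ]
        ct[m] = spec.ct_values[organ]
        pet[m] = spec.pid_per_cc(organ, t) / 100.0 * dose_kbq
    if spec.ct_noise_sd > 0:
        ct += rng.normal(0.0, spec.ct_noise_sd, spec.shape).astype(np.float32)
    if spec.pet_noise_sd_kbq_cc > 0:
        # plain additive noise; no clipping at zero, which would bias organ
        # means upward at low late-timepoint signal levels
        pet += rng.normal(0.0, spec.pet_noise_sd_kbq_cc,
                          spec.shape).astype(np.float32)

    affine = np.diag(list(spec.spacing) + [1.0])
    meta = AcquisitionMeta(
        subject_id=spec.subject_id, timepoint_h=t,
        injected_dose_mbq=spec.injected_dose_mbq,
        isotope_half_life_h=spec.isotope_half_life_h,
        body_weight_g=spec.body_weight_g, tumor_status=spec.tumor_status)
    ct_vol = ImageVolume(ct, spec.spacing, affine, "CT")
    pet_vol = ImageVolume(pet, spec.spacing, affine, "PET")
    label_map = LabelMap(labels, spec.spacing, affine, dict(ORGAN_TABLE))
    return ct_vol, pet_vol, label_map, meta


def analytic_truth(spec: PhantomSpec, t: float) -> dict[str, dict[str, float]]:
    """Closed-form per-organ PK values, independent of any rendered image.

    Volumes are exact ellipsoid volumes (4/3 pi abc); rasterized volumes
    converge to them as the grid is refined.
    """
    half = spec.half_fov_mm
    out = {}
    for organ in spec.organs:
        vol_mm3 = 0.0
        for ell in spec.geometry[organ]:
            _, r = ell.in_mm(half)
            vol_mm3 += 4.0 / 3.0 * np.pi * float(np.prod(r))
        vol_cc = vol_mm3 / 1000.0
        f = spec.pid_per_cc(organ, t)
        out[organ] = {
            "volume_cc": vol_cc,
            "pid_per_cc": f,
            "pid": f * vol_cc,
            "suv_mean": f / 100.0 * spec.body_weight_g,
        }
    return out


def randomized_spec(base: PhantomSpec, subject_id: str, tumor: bool,
                    rng: np.random.Generator,
                    slow_half_life_range=(5.0, 11.0)) -> PhantomSpec:
    """Per-subject variation: geometry jitter, kinetic amplitudes, dose.

    The slow-phase half-life is drawn once per subject and shared by all
    blood-pool organs (it models a single systemic clearance). Tumor
    bearing shifts splenic uptake up by 15% (documented off-target effect).
    """
    spec = copy.deepcopy(base)
    spec.subject_id = subject_id
    spec.tumor_status = "tumor_bearing" if tumor else "healthy"
    if not tumor:
        spec.geometry.pop("tumor", None)
    t_slow = float(rng.uniform(*slow_half_life_range))
    for organ, organs in spec.geometry.items():
        for e in organs:
            e.radii = tuple(float(r * rng.uniform(0.92, 1.08))
                            for r in e.radii)
    for organ, k in spec.kinetics.items():
        if isinstance(k, TwoPhase):
            k.a_fast *= float(rng.uniform(0.8, 1.2))
            k.a_slow *= float(rng.uniform(0.8, 1.2))
            k.t_half_slow_h = t_slow
        else:
            k.peak *= float(rng.uniform(0.8, 1.2))
            k.t_half_uptake_h *= float(rng.uniform(0.85, 1.15))
    if tumor:
        spec.kinetics["spleen"].peak *= 1.15
    spec.injected_dose_mbq = float(base.injected_dose_mbq
                                   * rng.uniform(0.9, 1.1))
    spec.body_weight_g = float(np.clip(rng.normal(22.0, 2.0), 16.0, 30.0))
    spec.seed = int(rng.integers(0, 2 ** 31 - 1))
    return spec


def generate_cohort(n_subjects: int, timepoints=DEFAULT_TIMEPOINTS,
                    tumor_fraction: float = 0.65, seed: int = 0,
                    out_dir=None, base_spec: PhantomSpec | None = None
                    ) -> tuple[list[PhantomSpec], DatasetManifest | None]:
    """Randomized cohort of phantoms; optionally written to disk.

    Writes ``out_dir/<subject>/<timepoint>/{ct,pet,labels}.nii.gz + meta.json``
    and returns the per-subject specs plus the manifest scanned back from
    disk (None when ``out_dir`` is None). Fully reproducible under ``seed``.
    """
    if n_subjects < 1:
        raise DataError("need at least one subject")
    if not len(tuple(timepoints)):
        raise DataError("need at least one timepoint")
    rng = np.random.default_rng(seed)
    base = base_spec or PhantomSpec()
    n_tumor = int(round(tumor_fraction * n_subjects))
    tumor_flags = np.zeros(n_subjects, dtype=bool)
    tumor_flags[:n_tumor] = True
    rng.shuffle(tumor_flags)
    specs = [randomized_spec(base, f"m{i:03d}", bool(tumor_flags[i]), rng)
             for i in range(n_subjects)]
    if out_dir is None:
        return specs, None
    out_dir = Path(out_dir)
    for spec in specs:
        for t in timepoints:
            case_dir = out_dir / spec.subject_id / f"{t:06.1f}h"
            case_dir.mkdir(parents=True, exist_ok=True)
            ct, pet, labels, meta = render_phantom(spec, t)
            write_volume(ct, case_dir / "ct.nii.gz")
            write_volume(pet, case_dir / "pet.nii.gz")
            write_labels(labels, case_dir / "labels.nii.gz")
            meta.to_json(case_dir / "meta.json")
    return specs, build_manifest(out_dir)
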