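"""NIfTI round-trips, affine registration, manifests and fold assignment."""

import numpy as np
import pandas as pd
import pytest

from pkseg.volume_io import (ORGAN_TABLE, AcquisitionMeta, DataError,
                             DatasetManifest, ImageVolume, LabelMap,
                             MANIFEST_COLUMNS, apply_affine_registration,
                             assign_folds, build_manifest, read_labels,
                             read_volume, write_labels, write_volume)


def _affine(spacing, origin=(0.0, 0.0, 0.0)):
    a = np.diag(list(spacing) + [1.0])
    a[:3, 3] = origin
    return a


@pytest.mark.parametrize("dtype", [np.float32, np.int16])
def test_write_read_roundtrip_bit_exact(tmp_path, dtype):
    rng = np.random.default_rng(0)
    if np.issubdtype(dtype, np.integer):
        data = rng.integers(-500, 500, size=(4, 4, 4)).astype(dtype)
    else:
        data = rng.normal(size=(4, 4, 4)).astype(dtype)
    spacing = (0.8, 0.15, 0.15)
    vol = ImageVolume(data, spacing, _affine(spacing, (1.0, -2.0, 3.0)), "CT")
    write_volume(vol, tmp_path / "v.nii.gz")
    back = read_volume(tmp_path / "v.nii.gz", "CT")
    assert back.data.dtype == dtype
    np.testing.assert_array_equal(back.data, data)
    np.testing.assert_allclose(back.spacing, spacing, rtol=1e-6)
    np.testing.assert_allclose(back.affine, vol.affine, atol=1e-5)


def test_non_3d_payload_rejected(tmp_path):
    import nibabel as nib
    nib.save(nib.Nifti1Image(np.zeros((4, 4)), np.eye(4)),
             str(tmp_path / "flat.nii.gz"))
    with pytest.raises(DataError, match="non-3D"):
        read_volume(tmp_path / "flat.nii.gz", "CT")
    with pytest.raises(DataError, match="no such file"):
        read_volume(tmp_path / "missing.nii.gz", "CT")


def test_label_roundtrip_and_table_validation(tmp_path):
    data = np.zeros((5, 5, 5), dtype=np.int16)
    data[1:3, 1:3, 1:3] = 2
    lm = LabelMap(data, (1, 1, 1), np.eye(4))
    write_labels(lm, tmp_path / "l.nii.gz")
    back = read_labels(tmp_path / "l.nii.gz")
    np.testing.assert_array_equal(back.data, data)
    with pytest.raises(DataError, match="organ table"):
        LabelMap(np.full((2, 2, 2), 9, dtype=np.int16), (1, 1, 1), np.eye(4))


def test_registration_identity_is_lossless():
    rng = np.random.default_rng(1)
    vol = ImageVolume(rng.normal(size=(6, 7, 8)).astype(np.float32),
                      (1.0, 0.5, 0.5), _affine((1.0, 0.5, 0.5)), "PET")
    out = apply_affine_registration(vol, np.eye(4), vol, "linear")
    np.testing.assert_allclose(out.data, vol.data, atol=1e-5)


def test_registration_translates_delta_spike_by_one_voxel():
    spacing = (2.0, 1.0, 1.0)
    data = np.zeros((8, 8, 8), dtype=np.float32)
    data[3, 4, 5] = 1.0
    vol = ImageVolume(data, spacing, _affine(spacing), "PET")
    t = np.eye(4)
    t[:3, 3] = spacing  # one-voxel world translation along each axis
    out = apply_affine_registration(vol, t, vol, "linear")
    expected = np.zeros_like(data)
    expected[4, 5, 6] = 1.0
    np.testing.assert_allclose(out.data, expected, atol=1e-5)


def test_registration_nearest_preserves_binary_mask_exactly():
    rng = np.random.default_rng(2)
    data = (rng.random((6, 6, 6)) > 0.7).astype(np.int16)
    lm = LabelMap(data, (1, 1, 1), np.eye(4))
    out = apply_affine_registration(lm, np.eye(4), lm, "nearest")
    np.testing.assert_array_equal(out.data, data)
    # linear interpolation of labels is refused outright
    with pytest.raises(DataError, match="nearest"):
        apply_affine_registration(lm, np.eye(4), lm, "linear")


def test_registration_never_invents_labels():
    rng = np.random.default_rng(3)
    data = rng.choice([0, 2, 5], size=(8, 8, 8)).astype(np.int16)
    lm = LabelMap(data, (1, 1, 1), np.eye(4))
    t = np.eye(4)
    t[:3, 3] = (0.3, -0.7, 1.2)
    out = apply_affine_registration(lm, t, lm, "nearest")
    assert set(np.unique(out.data)) <= set(np.unique(data))
    with pytest.raises(DataError, match="singular"):
        apply_affine_registration(lm, np.zeros((4, 4)), lm, "nearest")


# --------------------------------------------------------------------------
# manifests
# --------------------------------------------------------------------------

def _write_case(case_dir, subject, t, shape=(3, 3, 3)):
    case_dir.mkdir(parents=True)
    vol = ImageVolume(np.zeros(shape, dtype=np.float32), (1, 1, 1),
                      np.eye(4), "CT")
    write_volume(vol, case_dir / "ct.nii.gz")
    vol.modality = "PET"
    write_volume(vol, case_dir / "pet.nii.gz")
    write_labels(LabelMap(np.zeros(shape, dtype=np.int16), (1, 1, 1),
                          np.eye(4)), case_dir / "labels.nii.gz")
    AcquisitionMeta(subject, t, 8.0, 12.701, 22.0).to_json(
        case_dir / "meta.json")


def test_build_manifest_rows_and_order(tmp_path):
    for subject in ("m001", "m000"):
        for t in (24.0, 1.0):
            _write_case(tmp_path / subject / f"{t:06.1f}h", subject, t)
    mf = build_manifest(tmp_path)
    assert len(mf) == 4
    assert list(mf.frame["subject_id"]) == ["m000", "m000", "m001", "m001"]
    assert list(mf.frame["timepoint_h"]) == [1.0, 24.0, 1.0, 24.0]
    assert list(mf.frame.columns) == MANIFEST_COLUMNS


def test_build_manifest_empty_dir_and_orphans(tmp_path):
    assert len(build_manifest(tmp_path)) == 0
    case = tmp_path / "m000" / "0001.0h"
    _write_case(case, "m000", 1.0)
    (case / "pet.nii.gz").unlink()
    with pytest.raises(DataError, match="pet.nii.gz"):
        build_manifest(tmp_path)


def _fake_manifest(n_subjects, timepoints):
    rows = [{"subject_id": f"m{i:03d}", "timepoint_h": t,
             "ct_path": "x", "pet_path": "x", "labels_path": "x",
             "meta_path": "x", "tumor_status": "healthy", "fold": pd.NA}
            for i in range(n_subjects) for t in timepoints]
    frame = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    frame["fold"] = frame["fold"].astype("Int64")
    return DatasetManifest(frame)


def test_fold_assignment_by_subject_balances_and_partitions():
    mf = _fake_manifest(71, (1.0, 3.5, 6.0, 24.0, 48.0))
    out = assign_folds(mf, k=5, seed=3)
    frame = out.frame
    # every row lands in exactly one test fold; train membership is 4-fold
    assert frame["fold"].notna().all()
    counts = frame.groupby("subject_id")["fold"].nunique()
    assert (counts == 1).all()  # a subject's 5 timepoints stay together
    per_fold = frame.drop_duplicates("subject_id")["fold"].value_counts()
    assert sorted(per_fold) == [14, 14, 14, 14, 15]
    # identical seed reproduces the split; a different seed moves subjects
    again = assign_folds(mf, k=5, seed=3)
    assert (again.frame["fold"] == frame["fold"]).all()


def test_fold_assignment_by_volume_and_errors():
    mf = _fake_manifest(4, (1.0, 24.0))
    out = assign_folds(mf, k=2, seed=0, split_by="volume")
    sizes = out.frame["fold"].value_counts()
    assert sorted(sizes) == [4, 4]
    with pytest.raises(DataError, match="exceeds"):
        assign_folds(mf, k=5, seed=0)
    with pytest.raises(DataError, match="k must be"):
        assign_folds(mf, k=1, seed=0)


def test_acquisition_meta_validation_and_json(tmp_path):
    meta = AcquisitionMeta("m000", 3.5, 8.0, 12.701, 22.0, "tumor_bearing")
    meta.to_json(tmp_path / "m.json")
    assert AcquisitionMeta.from_json(tmp_path / "m.json") == meta
    with pytest.raises(DataError):
        AcquisitionMeta("m000", 3.5, -1.0, 12.701, 22.0)
    with pytest.raises(DataError):
        AcquisitionMeta("m000", -0.5, 8.0, 12.701, 22.0)
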