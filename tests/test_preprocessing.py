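"""Cropping, fingerprint normalization and resampling against hand oracles."""

import numpy as np
import pytest

from pkseg.phantom import analytic_truth
from pkseg.preprocessing import (CropBox, DatasetFingerprint,
                                 compute_foreground_box, fit_fingerprint,
                                 normalize_ct, normalize_pet, prepare_case,
                                 resample)
from pkseg.volume_io import DataError, ImageVolume, LabelMap


def _vol(data, spacing=(1.0, 1.0, 1.0), modality="CT"):
    return ImageVolume(np.asarray(data, dtype=np.float32), spacing,
                       np.diag(list(spacing) + [1.0]), modality)


class TestForegroundBox:
    def test_encloses_block_exactly(self):
        data = np.zeros((16, 16, 16), dtype=np.float32)
        data[3:11, 2:10, 5:13] = 100.0
        box = compute_foreground_box(_vol(data), threshold=50.0)
        # exhaustive-scan oracle
        idx = np.argwhere(data > 50.0)
        assert box.lo == tuple(idx.min(axis=0))
        assert box.hi == tuple(idx.max(axis=0) + 1)

    def test_all_foreground_gives_full_extent(self):
        box = compute_foreground_box(_vol(np.full((4, 5, 6), 10.0)),
                                     threshold=5.0)
        assert box.lo == (0, 0, 0) and box.hi == (4, 5, 6)

    def test_empty_foreground_errors(self):
        with pytest.raises(DataError, match="empty foreground"):
            compute_foreground_box(_vol(np.zeros((4, 4, 4))), threshold=50.0)

    def test_largest_component_wins(self):
        data = np.zeros((20, 10, 10), dtype=np.float32)
        data[1:3, 1:3, 1:3] = 100.0   # small distal blob ("head")
        data[8:18, 2:9, 2:9] = 100.0  # trunk
        box = compute_foreground_box(_vol(data), threshold=50.0)
        assert box.lo == (8, 2, 2) and box.hi == (18, 9, 9)


class TestFingerprint:
    def test_pooled_statistics_match_direct_computation(self):
        a = np.arange(100, dtype=np.float32).reshape(4, 5, 5)
        b = np.arange(100, 200, dtype=np.float32).reshape(4, 5, 5)
        boxes = [CropBox((0, 0, 0), (4, 5, 5))] * 2
        fp = fit_fingerprint([_vol(a), _vol(b)], boxes)
        pooled = np.concatenate([a.ravel(), b.ravel()])
        lo, hi = np.percentile(pooled, (0.5, 99.5))
        clipped = np.clip(pooled, lo, hi)
        assert fp.ct_clip_low == pytest.approx(lo)
        assert fp.ct_clip_high == pytest.approx(hi)
        assert fp.ct_mean == pytest.approx(clipped.mean())
        assert fp.ct_std == pytest.approx(clipped.std())
        # determinism
        fp2 = fit_fingerprint([_vol(a), _vol(b)], boxes)
        assert fp == fp2

    def test_constant_foreground_is_degenerate(self):
        vol = _vol(np.full((4, 4, 4), 7.0))
        with pytest.raises(DataError, match="degenerate|zero pooled"):
            fit_fingerprint([vol], [CropBox((0, 0, 0), (4, 4, 4))])

    def test_json_roundtrip(self, tmp_path):
        fp = DatasetFingerprint(-10.0, 250.0, 40.0, 30.0)
        fp.to_json(tmp_path / "fp.json")
        assert DatasetFingerprint.from_json(tmp_path / "fp.json") == fp


class TestNormalizeCT:
    FP = DatasetFingerprint(ct_clip_low=-100.0, ct_clip_high=300.0,
                            ct_mean=50.0, ct_std=25.0)

    def test_center_scale_and_clip(self):
        out = normalize_ct(_vol([[[50.0, 75.0, 400.0, 300.0]]]), self.FP)
        np.testing.assert_allclose(
            out.data[0, 0], [0.0, 1.0, 10.0, 10.0], atol=1e-6)
        # value above clip_high behaves exactly like clip_high itself


class TestNormalizePET:
    def test_hand_computed_case(self):
        out = normalize_pet(_vol([[[0.0, 0.0, 2.0, 2.0]]], modality="PET"))
        np.testing.assert_allclose(out.data[0, 0], [-1, -1, 1, 1], atol=1e-6)

    def test_zero_mean_unit_std_and_idempotence(self):
        rng = np.random.default_rng(0)
        vol = _vol(rng.normal(5, 3, (6, 6, 6)), modality="PET")
        out = normalize_pet(vol)
        assert abs(out.data.mean()) < 1e-6
        assert abs(out.data.std() - 1) < 1e-6
        again = normalize_pet(out)
        np.testing.assert_allclose(again.data, out.data, atol=1e-5)

    def test_constant_volume_errors(self):
        with pytest.raises(DataError, match="constant"):
            normalize_pet(_vol(np.full((3, 3, 3), 4.0), modality="PET"))


class TestResample:
    def test_shape_arithmetic(self):
        vol = _vol(np.random.default_rng(0).normal(size=(10, 10, 10)),
                   spacing=(1.6, 1.6, 1.6))
        out = resample(vol, (0.8, 0.8, 0.8))
        assert out.data.shape == (20, 20, 20)
        assert out.spacing == (0.8, 0.8, 0.8)

    def test_noop_at_target_spacing(self):
        vol = _vol(np.random.default_rng(1).normal(size=(8, 8, 8)))
        out = resample(vol, (1.0, 1.0, 1.0))
        np.testing.assert_allclose(out.data, vol.data, atol=1e-6)

    def test_binary_labels_stay_binary(self):
        data = (np.random.default_rng(2).random((9, 9, 9)) > 0.5)
        lm = LabelMap(data.astype(np.int16), (1.3, 1.3, 1.3),
                      np.diag([1.3, 1.3, 1.3, 1.0]))
        out = resample(lm, (1.0, 1.0, 1.0))
        assert set(np.unique(out.data)) <= {0, 1}

    def test_roundtrip_preserves_mean_for_smooth_input(self):
        z = np.linspace(0, np.pi, 24)
        data = np.sin(z)[:, None, None] * np.ones((24, 24, 24))
        vol = _vol(data, spacing=(1.0, 1.0, 1.0))
        down = resample(vol, (1.5, 1.5, 1.5))
        back = resample(down, (1.0, 1.0, 1.0))
        assert abs(back.data.mean() - data.mean()) / abs(data.mean()) < 0.01


class TestPrepareCase:
    def test_shared_grid_volumes_and_determinism(self, rendered_case,
                                                 phantom_spec):
        ct, pet, labels, _ = rendered_case
        from pkseg.preprocessing import compute_foreground_box
        box = compute_foreground_box(ct)
        fp = fit_fingerprint([ct], [box], target_spacing=(0.8, 0.3, 0.3))
        ct_p, pet_p, lab_p = prepare_case(ct, pet, labels, fp)
        assert ct_p.data.shape == pet_p.data.shape == lab_p.data.shape
        # cropping must not cut labeled organs
        assert set(np.unique(lab_p.data)) == set(np.unique(labels.data))
        truth = analytic_truth(phantom_spec, 6.0)
        vox_cc = lab_p.voxel_volume_cc
        for organ in phantom_spec.organs:
            vol = lab_p.mask(organ).sum() * vox_cc
            assert vol == pytest.approx(truth[organ]["volume_cc"], rel=0.05)
        ct_q, pet_q, lab_q = prepare_case(ct, pet, labels, fp)
        np.testing.assert_array_equal(ct_p.data, ct_q.data)
        np.testing.assert_array_equal(lab_p.data, lab_q.data)

    def test_grid_mismatch_rejected(self, rendered_case):
        ct, pet, labels, _ = rendered_case
        bad = _vol(np.zeros((4, 4, 4)), modality="PET")
        fp = DatasetFingerprint(-100, 300, 40, 25)
        with pytest.raises(DataError, match="common grid"):
            prepare_case(ct, bad, labels, fp)
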