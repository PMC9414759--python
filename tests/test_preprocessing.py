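"""Windowing, SVM channels, peak location and the stratified split."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ffhrisk as fr
from ffhrisk.preprocessing import (CHANNELS, InsufficientHistoryError,
                                   WINDOW_LEN, load_windows, save_windows)
from ffhrisk.synthetic_data import IMURecording


def make_recording(acc, gyro=None, code="NF01", category="NF"):
    acc = np.asarray(acc, dtype=float)
    if gyro is None:
        gyro = np.zeros_like(acc)
    return IMURecording(acc=acc, gyro=np.asarray(gyro, dtype=float),
                        sampling_rate=100, movement_code=code,
                        category=category, subject_id="S01", trial_index=0,
                        performer="human")


finite = st.floats(min_value=-1e3, max_value=1e3, allow_nan=False)


class TestComputeSVM:
    def test_known_values(self):
        assert fr.compute_svm(1, 0, 0) == 1.0
        assert fr.compute_svm(3, 4, 12) == 13.0

    @settings(max_examples=200, derandomize=True)
    @given(finite, finite, finite)
    def test_matches_independent_oracle(self, x, y, z):
        oracle = math.sqrt(x * x + y * y + z * z)
        assert fr.compute_svm(x, y, z) == pytest.approx(oracle, abs=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            fr.compute_svm(1.0, float("nan"), 0.0)


class TestFindPeak:
    def test_constant_recording_tie_breaks_earliest(self):
        rec = make_recording(np.tile([0, 0, 1.0], (200, 1)))
        idx, val = fr.find_peak(rec)
        assert idx == 0
        assert val == 1.0

    def test_injected_spike_located(self):
        acc = np.tile([0, 0, 1.0], (500, 1))
        acc[412] = [0, 0, 5.0]
        idx, val = fr.find_peak(make_recording(acc))
        assert (idx, val) == (412, 5.0)

    def test_empty_recording_rejected(self):
        with pytest.raises(ValueError):
            fr.find_peak(make_recording(np.empty((0, 3))))


class TestExtractWindow:
    def test_window_rows_are_samples_230_to_279(self):
        acc = np.zeros((400, 3))
        acc[:, 2] = np.arange(400) / 1000 + 1.0       # strictly increasing ASVM
        rec = make_recording(acc)
        win = fr.extract_window(rec, 300)
        assert win.matrix.shape == (WINDOW_LEN, len(CHANNELS)) == (50, 8)
        np.testing.assert_allclose(win.matrix[0, 2], acc[230, 2])
        np.testing.assert_allclose(win.matrix[-1, 2], acc[279, 2])
        assert win.target_peak == pytest.approx(acc[300, 2])

    def test_svm_channels_recomputable(self, small_windows):
        for win in small_windows[:20]:
            m = win.matrix
            np.testing.assert_allclose(
                m[:, 3], np.sqrt(m[:, 0] ** 2 + m[:, 1] ** 2 + m[:, 2] ** 2),
                atol=1e-12)
            np.testing.assert_allclose(
                m[:, 7], np.sqrt(m[:, 4] ** 2 + m[:, 5] ** 2 + m[:, 6] ** 2),
                atol=1e-12)

    def test_target_dominates_window(self, small_windows):
        for win in small_windows:
            assert win.target_peak >= win.matrix[:, 3].max()

    def test_early_peak_rejected_with_recording_named(self):
        rec = make_recording(np.tile([0, 0, 1.0], (200, 1)))
        with pytest.raises(InsufficientHistoryError,
                           match="insufficient pre-peak history.*NF01_S01_t0"):
            fr.extract_window(rec, 60)

    def test_hdf5_roundtrip(self, small_windows, tmp_path):
        path = tmp_path / "w.h5"
        save_windows(small_windows, path)
        back = load_windows(path)
        assert len(back) == len(small_windows)
        np.testing.assert_array_equal(back[3].matrix, small_windows[3].matrix)
        assert back[3].recording_id == small_windows[3].recording_id


def default_scale_manifest():
    """Manifest rows for the default study scale: 1260 human + 20 dummy."""
    rows = []
    codes = ([f"NF{i:02d}" for i in range(1, 16)]
             + [f"LF{i:02d}" for i in range(1, 6)] + ["HF03"])
    for code in codes:
        for s in range(20):
            for t in range(3):
                rows.append({"recording_id": f"{code}_S{s:02d}_t{t}",
                             "movement_code": code, "performer": "human"})
    for code in ("HF01", "HF02", "HF04", "HF05"):
        for t in range(5):
            rows.append({"recording_id": f"{code}_dummy_t{t}",
                         "movement_code": code, "performer": "dummy"})
    return pd.DataFrame(rows)


class TestSplit:
    def test_default_scale_counts_follow_floor_rule(self):
        split = fr.split_dataset(default_scale_manifest(), seed=0)
        manifest = default_scale_manifest()
        human = set(manifest.loc[manifest.performer == "human", "recording_id"])
        n_train_human = sum(1 for rid in split.train_ids if rid in human)
        n_train_dummy = len(split.train_ids) - n_train_human
        assert n_train_human == 882        # 21 codes x floor(0.7 * 60)
        assert n_train_dummy == 12         # 4 codes x floor(0.6 * 5)

    def test_partition_and_determinism(self):
        manifest = default_scale_manifest()
        s1 = fr.split_dataset(manifest, seed=4)
        s2 = fr.split_dataset(manifest, seed=4)
        assert s1 == s2
        ids = set(manifest["recording_id"])
        assert set(s1.train_ids) | set(s1.test_ids) == ids
        assert not set(s1.train_ids) & set(s1.test_ids)

    def test_per_stratum_fraction_close(self):
        manifest = default_scale_manifest()
        split = fr.split_dataset(manifest, seed=1)
        train = set(split.train_ids)
        for code, grp in manifest.groupby("movement_code"):
            frac = 0.7 if grp["performer"].iloc[0] == "human" else 0.6
            got = sum(1 for rid in grp["recording_id"] if rid in train) / len(grp)
            assert abs(got - frac) <= 1.0 / len(grp)

    @pytest.mark.parametrize("kwargs", [{"human_frac": 1.0}, {"human_frac": 0.0},
                                        {"dummy_frac": 1.2}])
    def test_degenerate_fractions_rejected(self, kwargs):
        with pytest.raises(ValueError):
            fr.split_dataset(default_scale_manifest(), **kwargs)


class TestZScore:
    def test_statistics_from_training_data_only(self, small_windows):
        train, test = small_windows[:30], small_windows[30:]
        ztrain, ztest, (mean, sd) = fr.preprocessing.zscore_windows(train, test)
        stacked = np.stack([w.matrix for w in ztrain])
        np.testing.assert_allclose(stacked.mean(axis=(0, 1)), 0.0, atol=1e-12)
        np.testing.assert_allclose(stacked.std(axis=(0, 1)), 1.0, atol=1e-12)
        # test windows use the train statistics, so they are not exactly 0/1
        np.testing.assert_allclose(ztest[0].matrix,
                                   (test[0].matrix - mean) / sd, atol=1e-12)
        assert ztest[0].target_peak == test[0].target_peak

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            fr.preprocessing.zscore_windows([])


class TestAssembleInputs:
    def test_shapes_per_architecture(self, small_windows):
        ten = small_windows[:10]
        for arch in ("cnn1d", "lstm", "convlstm"):
            X, y = fr.assemble_inputs(ten, arch)
            assert X.shape == (10, 50, 8) and y.shape == (10,)
        X, _ = fr.assemble_inputs(ten, "cnn2d")
        assert X.shape == (10, 50, 8, 1)

    def test_targets_aligned(self, small_windows):
        X, y = fr.assemble_inputs(small_windows[:5], "lstm")
        assert list(y) == [w.target_peak for w in small_windows[:5]]

    def test_empty_and_unknown_rejected(self, small_windows):
        with pytest.raises(ValueError):
            fr.assemble_inputs([], "cnn1d")
        with pytest.raises(ValueError):
            fr.assemble_inputs(small_windows[:2], "mlp")
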