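"""Generator: profiles, waveform invariants, dataset bookkeeping."""

import dataclasses

import numpy as np
import pytest

import ffhrisk as fr
from ffhrisk.synthetic_data import DUMMY_CODES, G_MS2, write_dataset


def measured_free_fall_s(rec, peak_idx):
    """Length of the contiguous weightless (< 0.5 g) run ending at the peak."""
    asvm = fr.compute_svm(*rec.acc.T)
    i = peak_idx - 1
    while i >= 0 and asvm[i] < 0.5:
        i -= 1
    return (peak_idx - 1 - i) / rec.sampling_rate


class TestProfiles:
    def test_exactly_25_profiles_by_category(self):
        profs = fr.default_profiles()
        assert len(profs) == 25
        cats = [p.category for p in profs]
        assert cats.count("NF") == 15
        assert cats.count("LF") == 5
        assert cats.count("HF") == 5
        assert len({p.code for p in profs}) == 25

    def test_performer_assignment(self, profiles_by_code):
        for code, p in profiles_by_code.items():
            assert p.performer == ("dummy" if code in DUMMY_CODES else "human")

    def test_peak_bounds_per_category(self, profiles_by_code):
        for code, p in profiles_by_code.items():
            assert p.peak_min <= p.peak_mean <= p.peak_max
            assert p.peak_sd > 0
            if p.category == "HF":
                assert p.peak_min >= 9.0
            elif code == "NF15":
                assert p.peak_min >= 5.0 and p.peak_max <= 9.0
            elif p.category == "NF":
                assert p.peak_max <= 4.0

    def test_forward_fall_exceeds_vertical_at_equal_height(self, profiles_by_code):
        assert (profiles_by_code["HF04"].peak_mean
                > profiles_by_code["HF01"].peak_mean)   # 2 m forward vs vertical
        assert (profiles_by_code["HF05"].peak_mean
                > profiles_by_code["HF02"].peak_mean)   # 3 m forward vs vertical

    def test_free_fall_flag_matches_height(self, profiles_by_code):
        for p in profiles_by_code.values():
            assert (p.fall_height > 0) == p.has_free_fall

    @pytest.mark.parametrize("bad", [
        {"peak_sd": 0.0},
        {"peak_min": 5.0, "peak_mean": 2.0},
        {"peak_mean": float("nan")},
        {"fall_height": 1.0},              # free-fall flag left False
        {"performer": "robot"},
    ])
    def test_invalid_profiles_rejected(self, profiles_by_code, bad):
        with pytest.raises(ValueError):
            dataclasses.replace(profiles_by_code["NF01"], **bad)


class TestGenerateRecording:
    def test_seeded_determinism(self, profiles_by_code):
        a = fr.generate_recording(profiles_by_code["LF03"], "S01", 0, 99)
        b = fr.generate_recording(profiles_by_code["LF03"], "S01", 0, 99)
        assert np.array_equal(a.acc, b.acc) and np.array_equal(a.gyro, b.gyro)

    def test_recording_invariants(self, profiles_by_code):
        rec = fr.generate_recording(profiles_by_code["NF10"], "S02", 1, 5)
        assert rec.sampling_rate == 100
        assert rec.n_samples >= 100
        assert np.isfinite(rec.acc).all() and np.isfinite(rec.gyro).all()
        idx, _ = fr.find_peak(rec)
        assert idx >= 70        # enough history for the pre-impact window

    def test_hf02_free_fall_duration_and_peak(self, profiles_by_code):
        rec = fr.generate_recording(profiles_by_code["HF02"], "dummy", 0, 42)
        idx, peak = fr.find_peak(rec)
        assert peak >= 9.0
        expected = np.sqrt(2 * 3.0 / G_MS2)     # 0.782 s for a 3 m drop
        assert measured_free_fall_s(rec, idx) == pytest.approx(expected, rel=0.2)

    def test_nf02_peak_in_working_range(self, profiles_by_code):
        rec = fr.generate_recording(profiles_by_code["NF02"], "S01", 1, 7)
        _, peak = fr.find_peak(rec)
        assert 1.0 <= peak <= 4.0

    def test_invalid_seed_rejected(self, profiles_by_code):
        with pytest.raises(ValueError, match="seed"):
            fr.generate_recording(profiles_by_code["NF01"], "S01", 0, 1.5)

    @pytest.mark.parametrize("code", ["NF01", "NF15", "LF01", "LF04", "HF03", "HF05"])
    def test_peak_containment_over_many_draws(self, profiles_by_code, code):
        """Measured global peaks always respect the profile's truncation bounds."""
        p = profiles_by_code[code]
        peaks = []
        for s in range(200):
            rec = fr.generate_recording(p, "S01", 0, 10_000 + s)
            peaks.append(fr.find_peak(rec)[1])
        assert min(peaks) >= p.peak_min
        assert max(peaks) <= p.peak_max

    def test_peak_is_unique_global_max(self, profiles_by_code):
        rec = fr.generate_recording(profiles_by_code["HF04"], "dummy", 2, 17)
        asvm = fr.compute_svm(*rec.acc.T)
        idx = int(np.argmax(asvm))
        others = np.delete(asvm, idx)
        assert asvm[idx] > others.max()


class TestGenerateDataset:
    def test_default_counts(self):
        spec = fr.DatasetSpec()
        # count without generating: 21 human codes x 20 subjects x 3 trials
        assert spec.n_subjects * 21 * spec.human_trials == 1260
        assert 4 * spec.dummy_trials == 20

    def test_small_spec_counts(self, small_dataset):
        recordings, manifest = small_dataset
        assert len(recordings) == 46          # 2 x 21 + 4
        assert (manifest["performer"] == "human").sum() == 42
        assert (manifest["performer"] == "dummy").sum() == 4
        assert set(manifest.columns) >= {"recording_id", "movement_code",
                                         "category", "performer", "subject_id",
                                         "trial_index", "seed"}

    def test_manifest_reproducible(self):
        spec = fr.DatasetSpec(n_subjects=1, human_trials=1, dummy_trials=1,
                              master_seed=3)
        _, m1 = fr.generate_dataset(spec)
        _, m2 = fr.generate_dataset(spec)
        assert m1.equals(m2)

    def test_written_csvs_byte_identical_across_reruns(self, tmp_path):
        spec = fr.DatasetSpec(n_subjects=1, human_trials=1, dummy_trials=1,
                              master_seed=11)
        for d in ("a", "b"):
            recs, manifest = fr.generate_dataset(spec)
            write_dataset(recs, manifest, tmp_path / d)
        for f in sorted((tmp_path / "a").rglob("*.csv")):
            twin = tmp_path / "b" / f.relative_to(tmp_path / "a")
            assert f.read_bytes() == twin.read_bytes()

    def test_zero_subjects_rejected(self):
        with pytest.raises(ValueError):
            fr.DatasetSpec(n_subjects=0)

    def test_category_separation(self, small_dataset):
        recordings, _ = small_dataset
        peaks = {"NF": [], "HF": []}
        for rec in recordings:
            if rec.category in peaks and rec.movement_code != "NF15":
                peaks[rec.category].append(fr.find_peak(rec)[1])
        assert np.mean(peaks["HF"]) > 9.0 > np.mean(peaks["NF"])
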