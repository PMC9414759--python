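"""Feature extraction for pre-impact prediction.

Each trial is reduced to a single 50-sample x 8-channel matrix: the raw
tri-axial acceleration and angular velocity plus their sum vector magnitudes
(A_SVM, G_SVM), taken from 0.7 s to 0.2 s before the impact peak at 100 Hz.
The regression target is the trial's peak A_SVM in g, which by construction
lies after the window.  Train/test assignment keeps 70% of human trials and
60% of dummy trials for training, stratified by movement type.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .synthetic_data import IMURecording

CHANNELS = ("AX", "AY", "AZ", "ASVM", "GX", "GY", "GZ", "GSVM")
WINDOW_PRE_SAMPLES = 70    # window starts 0.7 s before the peak
WINDOW_GAP_SAMPLES = 20    # and ends 0.2 s before it
WINDOW_LEN = WINDOW_PRE_SAMPLES - WINDOW_GAP_SAMPLES   # 50 samples = 0.5 s

ARCHITECTURES = ("cnn1d", "cnn2d", "lstm", "convlstm")

__all__ = [
    "CHANNELS", "WINDOW_LEN", "FeatureWindow", "SplitAssignment",
    "compute_svm", "find_peak", "extract_window", "windows_from_recordings",
    "split_dataset", "assemble_inputs", "save_windows", "load_windows",
    "zscore_windows",
]


class InsufficientHistoryError(ValueError):
    """Raised when a peak occurs too early for the pre-impact window."""


@dataclass(frozen=True)
class FeatureWindow:
    """50x8 pre-impact matrix with its regression target (peak A_SVM, g)."""

    matrix: np.ndarray
    target_peak: float
    movement_code: str
    category: str
    recording_id: str

    def __post_init__(self) -> None:
        if self.matrix.shape != (WINDOW_LEN, len(CHANNELS)):
            raise ValueError(
                f"{self.recording_id}: window must be {WINDOW_LEN}x{len(CHANNELS)}, "
                f"got {self.matrix.shape}")
        if not np.isfinite(self.matrix).all() or not np.isfinite(self.target_peak):
            raise ValueError(f"{self.recording_id}: non-finite window or target")


@dataclass(frozen=True)
class SplitAssignment:
    train_ids: tuple
    test_ids: tuple
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


def compute_svm(x, y, z):
    """Sum vector magnitude sqrt(x^2 + y^2 + z^2); elementwise on arrays."""
    x, y, z = np.asarray(x, dtype=float), np.asarray(y, dtype=float), np.asarray(z, dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all() and np.isfinite(z).all()):
        raise ValueError("compute_svm requires finite inputs")
    out = np.sqrt(x * x + y * y + z * z)
    return float(out) if out.ndim == 0 else out


def find_peak(recording: IMURecording) -> tuple[int, float]:
    """Index and value (g) of the global A_SVM maximum; earliest on ties."""
    if recording.n_samples == 0:
        raise ValueError("cannot locate a peak in an empty recording")
    asvm = compute_svm(recording.acc[:, 0], recording.acc[:, 1], recording.acc[:, 2])
    idx = int(np.argmax(asvm))          # np.argmax returns the first maximum
    return idx, float(asvm[idx])


def extract_window(recording: IMURecording, peak_index: int) -> FeatureWindow:
    """Cut the pre-impact window [peak-70, peak-20) and pair it with its target.

    The eight columns are AX, AY, AZ, ASVM, GX, GY, GZ, GSVM in that order.
    """
    if peak_index < WINDOW_PRE_SAMPLES:
        raise InsufficientHistoryError(
            f"insufficient pre-peak history in recording {recording.recording_id}: "
            f"peak at sample {peak_index}, need >= {WINDOW_PRE_SAMPLES}")
    sl = slice(peak_index - WINDOW_PRE_SAMPLES, peak_index - WINDOW_GAP_SAMPLES)
    acc = recording.acc[sl]
    gyro = recording.gyro[sl]
    asvm = compute_svm(acc[:, 0], acc[:, 1], acc[:, 2])
    gsvm = compute_svm(gyro[:, 0], gyro[:, 1], gyro[:, 2])
    matrix = np.column_stack([acc[:, 0], acc[:, 1], acc[:, 2], asvm,
                              gyro[:, 0], gyro[:, 1], gyro[:, 2], gsvm])
    target = compute_svm(*recording.acc[peak_index])
    return FeatureWindow(matrix=matrix, target_peak=float(target),
                         movement_code=recording.movement_code,
                         category=recording.category,
                         recording_id=recording.recording_id)


def windows_from_recordings(recordings) -> list[FeatureWindow]:
    """One window per recording, at its global A_SVM peak."""
    out = []
    for rec in recordings:
        idx, _ = find_peak(rec)
        out.append(extract_window(rec, idx))
    return out


def split_dataset(manifest: pd.DataFrame, human_frac: float = 0.7,
                  dummy_frac: float = 0.6, seed: int = 0) -> SplitAssignment:
    """Seeded stratified train/test split.

    Strata are movement codes; each stratum contributes
    floor(frac * stratum_size) recordings to training (frac = 70% for human
    movements, 60% for dummy movements), the remainder to test.
    """
    if manifest.empty:
        raise ValueError("manifest is empty")
    for name, frac in (("human_frac", human_frac), ("dummy_frac", dummy_frac)):
        if not (0.0 < frac < 1.0):
            raise ValueError(f"{name} must lie strictly in (0, 1), got {frac}")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for code in sorted(manifest["movement_code"].unique()):
        stratum = manifest[manifest["movement_code"] == code]
        performer = stratum["performer"].iloc[0]
        frac = human_frac if performer == "human" else dummy_frac
        ids = sorted(stratum["recording_id"])
        rng.shuffle(ids)
        n_train = int(np.floor(frac * len(ids)))
        train.extend(ids[:n_train])
        test.extend(ids[n_train:])
    return SplitAssignment(train_ids=tuple(sorted(train)),
                           test_ids=tuple(sorted(test)), seed=seed)


def assemble_inputs(windows, architecture: str) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into a model-ready batch with aligned targets.

    Sequence models (cnn1d, lstm, convlstm) receive (n, 50, 8); the 2D CNN
    receives single-channel images (n, 50, 8, 1).
    """
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}; expected one of {ARCHITECTURES}")
    windows = list(windows)
    if not windows:
        raise ValueError("no windows to assemble")
    mats, targets = [], []
    for w in windows:
        if w.matrix.shape != (WINDOW_LEN, len(CHANNELS)) or not np.isfinite(w.matrix).all():
            raise ValueError(f"malformed window for recording {w.recording_id}")
        mats.append(w.matrix)
        targets.append(w.target_peak)
    X = np.stack(mats)
    if architecture == "cnn2d":
        X = X[..., None]
    return X, np.asarray(targets, dtype=float)


def zscore_windows(train_windows, *window_sets):
    """Optional per-channel standardisation; statistics from training data only.

    Returns (standardised train windows, *standardised other sets, stats)
    where stats is a (mean, sd) pair of length-8 arrays.  Off by default in
    the pipeline: the reference protocol feeds raw channels to the models.
    """
    train_windows = list(train_windows)
    if not train_windows:
        raise ValueError("no training windows to compute statistics from")
    stacked = np.stack([w.matrix for w in train_windows])
    mean = stacked.mean(axis=(0, 1))
    sd = stacked.std(axis=(0, 1))
    sd = np.where(sd > 0, sd, 1.0)

    def apply(ws):
        return [FeatureWindow(matrix=(w.matrix - mean) / sd,
                              target_peak=w.target_peak,
                              movement_code=w.movement_code,
                              category=w.category,
                              recording_id=w.recording_id)
                for w in ws]

    out = [apply(train_windows)] + [apply(list(ws)) for ws in window_sets]
    return (*out, (mean, sd))


def save_windows(windows, path) -> None:
    """Persist windows to HDF5 (datasets: windows, targets, ids, codes, categories)."""
    windows = list(windows)
    X = np.stack([w.matrix for w in windows])
    y = np.array([w.target_peak for w in windows])
    str_dt = h5py.string_dtype()
    with h5py.File(path, "w") as f:
        f.create_dataset("windows", data=X)
        f.create_dataset("targets", data=y)
        f.create_dataset("ids", data=[w.recording_id for w in windows], dtype=str_dt)
        f.create_dataset("codes", data=[w.movement_code for w in windows], dtype=str_dt)
        f.create_dataset("categories", data=[w.category for w in windows], dtype=str_dt)


def load_windows(path) -> list[FeatureWindow]:
    with h5py.File(path, "r") as f:
        X = f["windows"][:]
        y = f["targets"][:]
        ids = [s.decode() for s in f["ids"][:]]
        codes = [s.decode() for s in f["codes"][:]]
        cats = [s.decode() for s in f["categories"][:]]
    return [FeatureWindow(matrix=X[i], target_peak=float(y[i]),
                          movement_code=codes[i], category=cats[i],
                          recording_id=ids[i])
            for i in range(len(ids))]
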