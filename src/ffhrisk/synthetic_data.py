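"""Seeded synthetic 6-axis IMU recordings for construction-site movements.

The study conditions emulated here are 25 movement types: 15 non-fall working
movements (NF01..NF15), 5 low-hazard ground-level falls (LF01..LF05) and 5
high-hazard falls from height (HF01..HF05), recorded by a trunk-mounted IMU at
100 Hz.  Peak sum-vector-magnitude acceleration (A_SVM, in g) structures the
classes: ordinary work stays in 1-4 g (5-9 g for the 0.7 m jump NF15), ground
trips/slips mostly 4-9 g with the forward/backward slips exceeding 10 g, and
falls from height reach 9 g or more, vertical landings milder than forward
ones at equal height.  Falls from 2-3 m are performed by an instrumented
dummy; everything else by human subjects (20 subjects x 3 trials; dummy
movements x 5 trials).

The waveform model is deliberately simple: gravity projection plus band-limited
noise, movement-specific low-frequency oscillation whose amplitude scales with
the drawn peak, a near-zero free-fall segment of duration sqrt(2h/g) for falls
from height, a 30 ms half-sine impact pulse realising the drawn peak exactly,
and decaying post-impact ringing.  Per-movement peaks follow truncated normal
distributions bounded by the class ranges above.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats as _stats

G_MS2 = 9.81
DEFAULT_FS = 100
DEFAULT_DURATION_S = 5.0

CATEGORIES = ("NF", "LF", "HF")
DUMMY_CODES = frozenset({"HF01", "HF02", "HF04", "HF05"})

__all__ = [
    "MovementProfile",
    "IMURecording",
    "DatasetSpec",
    "default_profiles",
    "generate_recording",
    "generate_dataset",
    "write_dataset",
    "DUMMY_CODES",
]


@dataclass(frozen=True)
class MovementProfile:
    """Generative parameters for one movement type."""

    code: str
    category: str
    performer: str
    peak_mean: float
    peak_sd: float
    peak_min: float
    peak_max: float
    fall_height: float = 0.0
    has_free_fall: bool = False
    gyro_intensity: float = 50.0
    activity_freq_hz: float = 1.0
    description: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}, got {self.category!r}")
        if self.performer not in ("human", "dummy"):
            raise ValueError(f"performer must be 'human' or 'dummy', got {self.performer!r}")
        for name in ("peak_mean", "peak_sd", "peak_min", "peak_max",
                     "fall_height", "gyro_intensity", "activity_freq_hz"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"profile field {name} is not finite: {v!r}")
        if not (self.peak_min <= self.peak_mean <= self.peak_max):
            raise ValueError(
                f"{self.code}: require peak_min <= peak_mean <= peak_max, "
                f"got {self.peak_min}, {self.peak_mean}, {self.peak_max}")
        if self.peak_sd <= 0:
            raise ValueError(f"{self.code}: peak_sd must be > 0")
        if (self.fall_height > 0) != self.has_free_fall:
            raise ValueError(f"{self.code}: fall_height > 0 must coincide with has_free_fall")


@dataclass(frozen=True)
class IMURecording:
    """One trial: 3-axis acceleration (g) and angular velocity (deg/s)."""

    acc: np.ndarray          # (n, 3) in g
    gyro: np.ndarray         # (n, 3) in deg/s
    sampling_rate: float
    movement_code: str
    category: str
    subject_id: str
    trial_index: int
    performer: str

    @property
    def n_samples(self) -> int:
        return self.acc.shape[0]

    @property
    def recording_id(self) -> str:
        return f"{self.movement_code}_{self.subject_id}_t{self.trial_index}"

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.n_samples) / self.sampling_rate
        return pd.DataFrame({
            "time_s": t,
            "acc_x_g": self.acc[:, 0], "acc_y_g": self.acc[:, 1], "acc_z_g": self.acc[:, 2],
            "gyro_x_dps": self.gyro[:, 0], "gyro_y_dps": self.gyro[:, 1],
            "gyro_z_dps": self.gyro[:, 2],
        })


@dataclass(frozen=True)
class DatasetSpec:
    """Sizes and seed of a full synthetic data collection."""

    n_subjects: int = 20
    human_trials: int = 3
    dummy_trials: int = 5
    master_seed: int = 0
    profile_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.human_trials < 1 or self.dummy_trials < 1:
            raise ValueError("trial counts must be >= 1")


_NF_DESCRIPTIONS = {
    "NF01": "Sitting quickly and getting up", "NF02": "Sitting and getting up comfortably",
    "NF03": "Going up and down the stairs", "NF04": "Going up and down a ladder",
    "NF05": "Working with a pickaxe", "NF06": "Lifting (front)", "NF07": "Lifting (back)",
    "NF08": "Lifting (side)", "NF09": "Moving up and down in an elevator",
    "NF10": "Walking on a beam", "NF11": "Walking on a beam with luggage",
    "NF12": "Shoveling", "NF13": "Stretching", "NF14": "Climbing up and down a scaffold",
    "NF15": "0.7 m jump",
}

# (peak_mean, peak_sd, gyro_intensity, activity_freq_hz) for ordinary work.
_NF_PARAMS = {
    "NF01": (2.4, 0.5, 60, 0.8), "NF02": (1.8, 0.4, 40, 0.5), "NF03": (2.6, 0.5, 80, 1.8),
    "NF04": (2.2, 0.4, 60, 1.2), "NF05": (3.0, 0.5, 90, 1.5), "NF06": (2.0, 0.4, 50, 0.7),
    "NF07": (2.0, 0.4, 50, 0.7), "NF08": (2.1, 0.4, 55, 0.7), "NF09": (1.6, 0.3, 20, 0.3),
    "NF10": (2.3, 0.4, 70, 2.0), "NF11": (2.5, 0.4, 70, 2.0), "NF12": (2.8, 0.5, 85, 1.4),
    "NF13": (1.7, 0.3, 45, 0.4), "NF14": (2.4, 0.4, 75, 1.6),
}


def default_profiles() -> list[MovementProfile]:
    """The 25 movement profiles: 15 NF + 5 LF + 5 HF.

    Peak distributions encode the class ranges (NF 1-4 g, NF15 5-9 g,
    LF01/02/05 4-9 g, LF03/04 10-13 g, HF 9-16 g); forward falls from height
    carry a +2 g mean over vertical falls at equal height, reflecting the
    larger transfer of mechanical energy when the trunk leads the impact.
    """
    profiles: list[MovementProfile] = []
    for code in sorted(_NF_PARAMS):
        mean, sd, gyro, freq = _NF_PARAMS[code]
        profiles.append(MovementProfile(
            code=code, category="NF", performer="human",
            peak_mean=mean, peak_sd=sd, peak_min=1.3, peak_max=4.0,
            gyro_intensity=gyro, activity_freq_hz=freq,
            description=_NF_DESCRIPTIONS[code]))
    profiles.append(MovementProfile(
        code="NF15", category="NF", performer="human",
        peak_mean=7.0, peak_sd=0.8, peak_min=5.0, peak_max=9.0,
        fall_height=0.7, has_free_fall=True, gyro_intensity=80,
        activity_freq_hz=1.0, description=_NF_DESCRIPTIONS["NF15"]))
    lf = [
        ("LF01", "Forward trip", 6.5, 1.1, 4.0, 9.0, 250),
        ("LF02", "Lateral trip", 6.2, 1.1, 4.0, 9.0, 250),
        ("LF03", "Forward slip", 11.5, 0.7, 10.0, 13.0, 300),
        ("LF04", "Backward slip", 11.3, 0.7, 10.0, 13.0, 300),
        ("LF05", "Fainting", 5.8, 1.0, 4.0, 9.0, 150),
    ]
    for code, desc, mean, sd, lo, hi, gyro in lf:
        profiles.append(MovementProfile(
            code=code, category="LF", performer="human",
            peak_mean=mean, peak_sd=sd, peak_min=lo, peak_max=hi,
            gyro_intensity=gyro, activity_freq_hz=1.5, description=desc))
    hf = [
        # code, desc, height m, forward?, mean g
        ("HF01", "2 m vertical FFH", 2.0, False, 10.5),
        ("HF02", "3 m vertical FFH", 3.0, False, 11.5),
        ("HF03", "0.7 m forward FFH", 0.7, True, 10.0),
        ("HF04", "2 m forward FFH", 2.0, True, 12.5),
        ("HF05", "3 m forward FFH", 3.0, True, 13.5),
    ]
    for code, desc, height, forward, mean in hf:
        profiles.append(MovementProfile(
            code=code, category="HF",
            performer="dummy" if code in DUMMY_CODES else "human",
            peak_mean=mean, peak_sd=0.8, peak_min=9.0, peak_max=16.0,
            fall_height=height, has_free_fall=True,
            gyro_intensity=350.0 if forward else 40.0,
            activity_freq_hz=1.0, description=desc))
    assert len(profiles) == 25
    return profiles


def _lowpass(x: np.ndarray, cutoff_hz: float, fs: float) -> np.ndarray:
    b, a = _signal.butter(2, cutoff_hz, btype="low", fs=fs)
    return _signal.filtfilt(b, a, x, axis=0)


def _draw_peak(profile: MovementProfile, rng: np.random.Generator) -> float:
    a = (profile.peak_min - profile.peak_mean) / profile.peak_sd
    b = (profile.peak_max - profile.peak_mean) / profile.peak_sd
    return float(_stats.truncnorm.rvs(a, b, loc=profile.peak_mean,
                                      scale=profile.peak_sd, random_state=rng))


def _svm(v: np.ndarray) -> np.ndarray:
    return np.sqrt(np.sum(v * v, axis=1))


def generate_recording(profile: MovementProfile, subject_id: str,
                       trial_index: int, seed: int,
                       duration_s: float = DEFAULT_DURATION_S,
                       sampling_rate: float = DEFAULT_FS) -> IMURecording:
    """Synthesise one seeded 6-axis trial for a movement profile.

    The global A_SVM maximum is placed 2-4 s into the 5 s trial and equals a
    peak drawn from the profile's truncated normal; every other sample stays
    strictly below it, so the pre-impact window (which ends 0.2 s before the
    peak) never contains the peak itself.  Movements with a free-fall phase
    get a near-weightless segment of duration sqrt(2h/g) ending at impact.
    Identical arguments reproduce bit-identical output.
    """
    if not isinstance(seed, (int, np.integer)) or isinstance(seed, bool):
        raise ValueError(f"seed must be an integer, got {seed!r}")
    if seed < 0:
        raise ValueError(f"seed must be non-negative, got {seed}")
    fs = float(sampling_rate)
    n = int(round(duration_s * fs))
    if n < 100:
        raise ValueError("duration too short: need at least 100 samples")
    rng = np.random.default_rng(seed)

    peak = _draw_peak(profile, rng)
    peak_idx = int(rng.integers(int(2.0 * fs), int(4.0 * fs)))

    gravity = np.zeros((n, 3))
    gravity[:, 2] = 1.0
    noise = _lowpass(rng.normal(0.0, 0.05, (n, 3)), 15.0, fs)

    # Movement-specific oscillation whose amplitude tracks the drawn peak, so
    # the pre-impact window carries a cue about impact severity.
    t = np.arange(n) / fs
    activity = np.zeros((n, 3))
    amp = 0.30 * max(peak - 1.0, 0.1)
    if profile.category == "NF":
        env = np.clip(np.sin(np.pi * np.clip((t - 0.5) / (duration_s - 1.0), 0, 1)), 0, 1)
        phase = rng.uniform(0, 2 * np.pi, 3)
        f0 = profile.activity_freq_hz
        for ax in range(3):
            activity[:, ax] = amp * env * np.sin(2 * np.pi * f0 * t + phase[ax]) * (0.6 + 0.4 * rng.random())
    else:
        # trips/slips/falls: quiet activity, then a growing stumble before impact
        env = np.clip(np.sin(np.pi * np.clip((t - 0.5) / (duration_s - 1.0), 0, 1)), 0, 1)
        phase = rng.uniform(0, 2 * np.pi, 3)
        for ax in range(3):
            activity[:, ax] = 0.15 * env * np.sin(2 * np.pi * 1.0 * t + phase[ax])
        pre = slice(max(peak_idx - 50, 0), peak_idx)
        ramp = np.linspace(0, 1, peak_idx - pre.start)
        stumble_amp = 0.12 * max(peak - 1.0, 0.5)
        for ax in range(3):
            activity[pre, ax] += stumble_amp * ramp * np.sin(
                2 * np.pi * 4.0 * t[pre] + phase[ax])

    # post-impact ringing, decaying back to rest
    ring_len = min(int(0.6 * fs), n - peak_idx - 2)
    if ring_len > 2:
        rt = np.arange(ring_len) / fs
        ring = 0.25 * max(peak - 1.0, 0.1) * np.exp(-rt / 0.12) * np.sin(2 * np.pi * 9.0 * rt)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        activity[peak_idx + 2: peak_idx + 2 + ring_len] += ring[:, None] * direction[None, :]

    acc = gravity + noise + activity

    n_ff = 0
    if profile.has_free_fall:
        t_ff = np.sqrt(2.0 * profile.fall_height / G_MS2)
        n_ff = int(round(t_ff * fs))
        ff = slice(peak_idx - n_ff, peak_idx)
        acc[ff] = rng.normal(0.0, 0.02, (n_ff, 3))

    # Cap everything outside the impact pulse strictly below the drawn peak.
    protect = np.zeros(n, dtype=bool)
    if n_ff:
        protect[peak_idx - n_ff: peak_idx] = True
    cap = 0.90 * peak
    for _ in range(8):
        asvm = _svm(acc)
        over = (asvm > cap) & ~protect
        if not over.any():
            break
        dyn = acc[over] - gravity[over]
        acc[over] = gravity[over] + 0.8 * dyn

    # Half-sine impact pulse (30 ms) realising the drawn peak exactly.
    base = acc[peak_idx]
    base_norm = np.linalg.norm(base)
    if base_norm > 0.1:
        u = base / base_norm
    else:
        u = np.array([0.8, 0.1, -0.6]) if profile.gyro_intensity > 100 else np.array([0.0, 0.0, -1.0])
        u = u / np.linalg.norm(u)
    dot = float(base @ u)
    amp_pulse = -dot + np.sqrt(dot * dot + peak ** 2 - base_norm ** 2)
    w = max(int(round(0.030 * fs)), 1)          # 30 ms pulse width
    weights = np.sin(np.pi * np.arange(1, w + 1) / (w + 1))
    center = int(np.argmax(weights))
    start = peak_idx - center
    for k in range(w):
        i = start + k
        if i == peak_idx or not (0 <= i < n):
            continue
        if i < peak_idx and protect[i]:
            continue    # keep the free-fall segment weightless up to impact
        acc[i] = acc[i] + 0.95 * weights[k] * amp_pulse * u
    acc[peak_idx] = base + amp_pulse * u

    # Gyro: baseline noise, activity bursts scaled to the profile, and a
    # rotation burst around impact (large for forward falls, small vertical).
    gyro = _lowpass(rng.normal(0.0, 2.0, (n, 3)), 20.0, fs)
    gyro_env = np.abs(activity) / max(np.abs(activity).max(), 1e-9)
    gyro += profile.gyro_intensity * 0.4 * gyro_env * rng.uniform(0.5, 1.0, 3)[None, :]
    if profile.category != "NF" or profile.has_free_fall:
        burst_len = min(int(0.4 * fs), peak_idx)
        bt = np.arange(burst_len) / fs
        burst = profile.gyro_intensity * (peak / profile.peak_mean) * np.sin(
            np.pi * bt / bt[-1]) if burst_len > 1 else np.zeros(burst_len)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        gyro[peak_idx - burst_len: peak_idx] += burst[:, None] * axis[None, :]

    acc = np.ascontiguousarray(acc)
    gyro = np.ascontiguousarray(np.clip(gyro, -2000, 2000))
    if not (np.isfinite(acc).all() and np.isfinite(gyro).all()):
        raise RuntimeError("generated recording contains non-finite samples")
    return IMURecording(acc=acc, gyro=gyro, sampling_rate=fs,
                        movement_code=profile.code, category=profile.category,
                        subject_id=subject_id, trial_index=trial_index,
                        performer=profile.performer)


def _recording_seed(master_seed: int, code: str, subject_id: str, trial: int) -> int:
    """Stable per-recording substream seed (insertion-order independent)."""
    h = zlib.crc32(f"{code}|{subject_id}|{trial}".encode())
    return int(np.random.SeedSequence([master_seed, h]).generate_state(1)[0] % (2 ** 31))


def apply_overrides(profile: MovementProfile, overrides: dict) -> MovementProfile:
    return replace(profile, **overrides) if overrides else profile


def generate_dataset(spec: DatasetSpec,
                     profiles: Iterable[MovementProfile] | None = None
                     ) -> tuple[list[IMURecording], pd.DataFrame]:
    """Generate the full labelled collection plus its manifest.

    Human movements (21 types) are recorded by every synthetic subject
    `human_trials` times; the four dummy movements are recorded
    `dummy_trials` times by the single dummy.
    """
    if profiles is None:
        profiles = default_profiles()
    profiles = [apply_overrides(p, spec.profile_overrides.get(p.code, {}))
                for p in profiles]
    recordings: list[IMURecording] = []
    rows = []
    for prof in profiles:
        if prof.performer == "human":
            subjects = [f"S{i + 1:02d}" for i in range(spec.n_subjects)]
            n_trials = spec.human_trials
        else:
            subjects = ["dummy"]
            n_trials = spec.dummy_trials
        for subj in subjects:
            for trial in range(n_trials):
                seed = _recording_seed(spec.master_seed, prof.code, subj, trial)
                rec = generate_recording(prof, subj, trial, seed)
                recordings.append(rec)
                rows.append({
                    "recording_id": rec.recording_id,
                    "movement_code": prof.code,
                    "category": prof.category,
                    "performer": prof.performer,
                    "subject_id": subj,
                    "trial_index": trial,
                    "seed": seed,
                })
    manifest = pd.DataFrame(rows)
    return recordings, manifest


def write_dataset(recordings: list[IMURecording], manifest: pd.DataFrame,
                  outdir) -> pd.DataFrame:
    """Write one CSV per recording plus the manifest; returns manifest with paths."""
    from pathlib import Path
    outdir = Path(outdir)
    rec_dir = outdir / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recordings:
        path = rec_dir / f"{rec.recording_id}.csv"
        rec.to_frame().to_csv(path, index=False, float_format="%.6f")
        paths.append(str(path.relative_to(outdir)))
    manifest = manifest.copy()
    manifest.insert(1, "path", paths)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def read_recording(path, manifest_row) -> IMURecording:
    """Load one recording CSV back into an IMURecording."""
    df = pd.read_csv(path)
    acc = df[["acc_x_g", "acc_y_g", "acc_z_g"]].to_numpy()
    gyro = df[["gyro_x_dps", "gyro_y_dps", "gyro_z_dps"]].to_numpy()
    dt = np.diff(df["time_s"].to_numpy()[:2])[0]
    return IMURecording(acc=acc, gyro=gyro, sampling_rate=round(1.0 / dt),
                        movement_code=manifest_row["movement_code"],
                        category=manifest_row["category"],
                        subject_id=manifest_row["subject_id"],
                        trial_index=int(manifest_row["trial_index"]),
                        performer=manifest_row["performer"])
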