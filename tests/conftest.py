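import numpy as np
import pytest

import ffhrisk as fr
from ffhrisk.preprocessing import FeatureWindow


@pytest.fixture(scope="session")
def profiles_by_code():
    return {p.code: p for p in fr.default_profiles()}


@pytest.fixture(scope="session")
def small_dataset():
    """2 subjects x 1 trial (+1 dummy trial): 42 human + 4 dummy recordings."""
    spec = fr.DatasetSpec(n_subjects=2, human_trials=1, dummy_trials=1,
                          master_seed=7)
    return fr.generate_dataset(spec)


@pytest.fixture(scope="session")
def small_windows(small_dataset):
    recordings, _ = small_dataset
    return fr.windows_from_recordings(recordings)


def make_random_windows(n, rng, code="NF01", category="NF"):
    """Synthetic random feature windows whose target is the ASVM max + 1.

    Used as a separable toy regression task: the label is a deterministic
    function of the window itself.
    """
    wins = []
    for i in range(n):
        acc = rng.normal(scale=rng.uniform(0.5, 4.0), size=(50, 3))
        gyro = rng.normal(scale=5.0, size=(50, 3))
        asvm = np.sqrt((acc ** 2).sum(axis=1))
        gsvm = np.sqrt((gyro ** 2).sum(axis=1))
        mat = np.column_stack([acc, asvm, gyro, gsvm])
        wins.append(FeatureWindow(matrix=mat, target_peak=float(asvm.max() + 1.0),
                                  movement_code=code, category=category,
                                  recording_id=f"toy{i:03d}"))
    return wins


@pytest.fixture(scope="session")
def toy_windows():
    """200 generator windows relabelled with a separable target: the window's
    own ASVM-column maximum plus 1 g."""
    profiles = fr.default_profiles()
    wins = []
    for i in range(200):
        rec = fr.generate_recording(profiles[i % 25], "S01", 0, 5000 + i)
        idx, _ = fr.find_peak(rec)
        w = fr.extract_window(rec, idx)
        wins.append(FeatureWindow(
            matrix=w.matrix, target_peak=float(w.matrix[:, 3].max() + 1.0),
            movement_code=w.movement_code, category=w.category,
            recording_id=f"toy{i:03d}"))
    return wins


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
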