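import numpy as np
import pytest

from hippofeat.features import extract_cohort_features, grouped_task_reduce
from hippofeat.simulate import BurstCalibrator, GroupParams, generate_cohort

FS = 2000.0


@pytest.fixture(scope="session")
def fs() -> float:
    return FS


@pytest.fixture(scope="session")
def calibrator() -> BurstCalibrator:
    """One shared burst calibrator (probe fitting is the expensive part)."""
    return BurstCalibrator(FS, seed=2024)


@pytest.fixture(scope="session")
def small_cohort(calibrator):
    """A small default-parameter cohort with ground truth: 2 EH + 2 NEH
    hippocampi, 2 contacts each, rest + task, 40 s segments."""
    segments, truth = generate_cohort(
        (2, 2), 2, ("rest", "task"), GroupParams.table_defaults(),
        duration_s=40.0, fs=FS, seed=77, calibrator=calibrator,
    )
    return segments, truth


@pytest.fixture(scope="session")
def cohort_features(small_cohort):
    segments, _ = small_cohort
    return grouped_task_reduce(extract_cohort_features(segments))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
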