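import numpy as np
import pytest

from kmargin.types import AugmentationConfig, ClassCatalog, MonitoringRecord


@pytest.fixture
def catalog4():
    """Four-class catalog with the skewed composition of a realistic AF study."""
    return ClassCatalog(labels=("N", "A", "O", "P"), counts=(5050, 738, 2456, 284))


@pytest.fixture
def catalog3():
    return ClassCatalog(labels=("regular", "irregular", "noise"))


@pytest.fixture
def small_aug():
    return AugmentationConfig(window=1500, max_stride=500, fragment_len=300, test_stride=300)


@pytest.fixture
def ramp_record():
    """Single-channel record whose sample values equal their index."""
    sig = np.arange(6600, dtype=float)[None, :]
    return MonitoringRecord(id="ramp", signal=sig, sampling_rate=300.0, label="N")


def brute_force_window_count(length: int, window: int, stride: int) -> int:
    """Enumeration oracle: count offsets o with o + window <= length."""
    if length < window:
        return 1
    return len([o for o in range(0, length + 1, stride) if o + window <= length])
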