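import numpy as np
import pytest

from sigdict import EEGRecord, SeizureAnnotation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_record(rng):
    """Small 3-channel record, 200 s at 256 Hz, with two seizure intervals."""
    fs = 256
    n = 200 * fs
    samples = rng.standard_normal((3, n))
    return EEGRecord(
        samples=samples,
        channel_labels=("CH01", "CH02", "CH03"),
        sampling_rate=fs,
        annotations=[SeizureAnnotation(40.0, 60.0), SeizureAnnotation(120.0, 150.0)],
        patient_id="toy",
    )


def eeg_like_segment(rng, n=1024, ar=0.9):
    """AR(1)-correlated noise segment, the shape EMD sees in background EEG."""
    from scipy.signal import lfilter

    return lfilter([1.0], [1.0, -ar], rng.standard_normal(n))
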