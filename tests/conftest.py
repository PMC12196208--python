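import numpy as np
import pytest

from eegfusion.core import MONTAGE_19, EEGRecording


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_recording(rng, fs=500.0, duration_s=10.0, label="C", subject_id="sub-X",
                   with_reference=False):
    n = int(duration_s * fs)
    sig = rng.standard_normal((len(MONTAGE_19), n)) * 10.0
    ref = rng.standard_normal((2, n)) * 5.0 if with_reference else None
    return EEGRecording(subject_id=subject_id, label=label, fs=fs,
                        channels=MONTAGE_19, signal=sig, reference_pair=ref)


@pytest.fixture()
def recording(rng):
    return make_recording(rng)
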