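import numpy as np
import pytest

from afibnet.records import ECGRecord
from afibnet.synth import RhythmParams, SynthConfig, generate_record


@pytest.fixture
def sinus_record() -> ECGRecord:
    """Clean normal-sinus record: 60 bpm, 10 s at 250 Hz."""
    cfg = SynthConfig(fs=250, duration=10.0,
                      rhythm=RhythmParams.normal_sinus(mean_hr=60, rr_cv=0.0), seed=1)
    return generate_record(cfg)


@pytest.fixture
def af_record() -> ECGRecord:
    """AF record: 90 bpm, CV 0.25, 20 s at 300 Hz (>= 20 beats)."""
    cfg = SynthConfig(fs=300, duration=20.0,
                      rhythm=RhythmParams.atrial_fibrillation(mean_hr=90, rr_cv=0.25),
                      seed=5)
    return generate_record(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
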