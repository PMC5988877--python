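import numpy as np
import pytest

from fetalbss.io_formats import MultichannelRecord
from fetalbss.preprocess import bandpass_filter
from fetalbss.synthetic import canonical_mixture, make_beat_template, synth_source

CANONICAL_SEED = 11


@pytest.fixture(scope="session")
def canonical_fixture():
    """Calibrated noisy fixture: 4 abdominal channels + direct, WM ~ 10.9 dB,
    WF ~ 3.9 dB, 60 s at 1 kHz, plus ground-truth annotations."""
    record, m_ann, f_ann, true_A = canonical_mixture(
        seed=CANONICAL_SEED, duration_s=60.0, fs=1000.0)
    return record, m_ann, f_ann, true_A


@pytest.fixture(scope="session")
def noise_free_fixture():
    """Noise-free mixture at 500 Hz (rank 2) with the raw sources."""
    fs, dur = 500.0, 20.0
    record, m_ann, f_ann, true_A = canonical_mixture(
        seed=CANONICAL_SEED, duration_s=dur, fs=fs, noise_free=True)
    s_m, _ = synth_source(make_beat_template("maternal"), fs, dur)
    fetal = make_beat_template("fetal")
    s_f_raw, _ = synth_source(fetal, fs, dur)
    return record, m_ann, f_ann, s_m, s_f_raw


@pytest.fixture(scope="session")
def clean_fetal(noise_free_fixture):
    """Raw and 3-150 Hz bandpassed clean fetal source at 500 Hz."""
    _, _, _, _, s_f = noise_free_fixture
    filtered = bandpass_filter(MultichannelRecord(s_f[None, :], 500.0)).signals[0]
    return s_f, filtered


def correlate_abs(a: np.ndarray, b: np.ndarray) -> float:
    return float(abs(np.corrcoef(a, b)[0, 1]))
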