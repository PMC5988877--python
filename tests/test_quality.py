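import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fetalbss.io_formats import AnnotationSet
from fetalbss.quality import (coincidence_filter, compute_quality, fetal_power,
                              maternal_power, noise_power, quality_indices)

FS = 1000.0


def _ann(peaks, wave_class):
    return AnnotationSet(np.asarray(peaks), wave_class=wave_class)


def test_coincidence_disjoint_kept():
    j, i = coincidence_filter(_ann([1000], "maternal"), _ann([5000], "fetal"), FS)
    assert j.peaks.tolist() == [1000]
    assert i.peaks.tolist() == [5000]


def test_coincidence_overlap_removed():
    # |delta| = 30 ms < (100+40)/2 = 70 ms -> both windows overlap
    j, i = coincidence_filter(_ann([1000], "maternal"), _ann([1030], "fetal"), FS)
    assert len(j) == 0 and len(i) == 0


def test_coincidence_boundary():
    # 71 ms separation > 70 ms -> kept; 70 ms -> inclusive windows touch -> removed
    j, i = coincidence_filter(_ann([1000], "maternal"), _ann([1071], "fetal"), FS)
    assert len(j) == 1 and len(i) == 1
    j2, i2 = coincidence_filter(_ann([1000], "maternal"), _ann([1070], "fetal"), FS)
    assert len(j2) == 0 and len(i2) == 0


def test_noise_power_constant_signal():
    x = np.full(10000, 2.0)
    PN, L = noise_power(x, _ann([2000], "maternal"), _ann([5000], "fetal"), FS)
    assert PN == pytest.approx(4.0)
    assert L == 10000 - 101 - 41


def test_noise_power_no_annotations():
    x = np.arange(100, dtype=float)
    PN, L = noise_power(x, _ann([], "maternal"), _ann([], "fetal"), FS)
    assert PN == pytest.approx(np.mean(x ** 2))
    assert L == 100


def test_noise_power_gaussian_calibration():
    rng = np.random.default_rng(7)
    x = rng.standard_normal(60000)
    m = _ann(np.arange(2000, 58000, 1000), "maternal")
    f = _ann(np.arange(2430, 57000, 1000), "fetal")
    PN, _ = noise_power(x, m, f, FS)
    assert 0.97 <= PN <= 1.03


def test_maternal_power_constant_closed_form():
    # x = 3 inside maternal windows -> in-window mean power 9; PM = 9 - PN
    x = np.zeros(10000)
    j = _ann([2000, 7000], "maternal")
    for p in j.peaks:
        x[p - 50: p + 51] = 3.0
    assert maternal_power(x, j, PN=4.0, fs=FS) == pytest.approx(5.0)


def test_fetal_power_constant_closed_form():
    x = np.zeros(10000)
    i = _ann([3000], "fetal")
    x[3000 - 20: 3000 + 21] = 3.0
    assert fetal_power(x, i, PN=4.0, fs=FS) == pytest.approx(5.0)


def test_power_with_empty_window_set_rejected():
    with pytest.raises(ValueError):
        maternal_power(np.ones(1000), _ann([], "maternal"), 0.5, FS)


def test_negative_power_floored_with_warning():
    x = np.zeros(5000)
    j = _ann([2000], "maternal")
    with pytest.warns(UserWarning, match="floored"):
        assert maternal_power(x, j, PN=1.0, fs=FS) == 0.0


def test_quality_index_closed_forms():
    wmf, wm, wf = quality_indices(PM=40.0, PF=4.0, PN=4.0)
    assert wm == pytest.approx(10.0)
    assert wf == pytest.approx(0.0)
    assert wmf == pytest.approx(10.0)
    assert quality_indices(PM=5.0, PF=5.0, PN=1.0)[0] == pytest.approx(0.0)


def test_quality_index_invalid_powers():
    with pytest.raises(ValueError):
        quality_indices(0.0, 1.0, 1.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(pm=st.floats(1e-6, 1e6), pf=st.floats(1e-6, 1e6), pn=st.floats(1e-6, 1e6))
def test_wmf_identity(pm, pf, pn):
    wmf, wm, wf = quality_indices(pm, pf, pn)
    assert wmf == pytest.approx(wm - wf, abs=1e-9)


def test_amplitude_doubling_shifts_snr_not_wmf(canonical_fixture):
    record, m_ann, f_ann, _ = canonical_fixture
    x = record.signals[0]
    q1 = compute_quality(x, m_ann, f_ann, record.fs)
    q2 = compute_quality(2.0 * x, m_ann, f_ann, record.fs)
    assert q2.WM - q1.WM == pytest.approx(0.0, abs=1e-9)  # PM and PN both x4
    assert q2.WMF == pytest.approx(q1.WMF, abs=1e-9)
    # scaling only the in-window content by 2 adds ~6.02 dB instead
    x3 = x.copy()
    from fetalbss.quality import _window_mask
    mask = _window_mask(x3.size, m_ann, record.fs)
    x3[mask] = x[mask] * 2.0 - 0  # doubles maternal windows only
    q3 = compute_quality(x3, m_ann, f_ann, record.fs)
    assert q3.WM > q1.WM + 3.0


def test_injected_maternal_power_recovered():
    from fetalbss.synthetic import make_beat_template, synth_source
    s_m, m_ann = synth_source(make_beat_template("maternal"), FS, 60.0)
    rng = np.random.default_rng(5)
    x = s_m + 0.1 * rng.standard_normal(s_m.size)
    f_ann = _ann([], "fetal")
    j, _ = coincidence_filter(m_ann, f_ann, FS)
    PN, _ = noise_power(x, m_ann, f_ann, FS)
    PM = maternal_power(x, j, PN, FS)
    # generator truth: mean maternal power over the same windows
    truth = []
    for p in j.peaks:
        truth.append(np.mean(s_m[p - 50: p + 51] ** 2))
    assert PM == pytest.approx(np.mean(truth), rel=0.10)


def test_full_report_on_canonical_fixture(canonical_fixture):
    record, m_ann, f_ann, _ = canonical_fixture
    q = compute_quality(record.signals[0], m_ann, f_ann, record.fs)
    assert q.WM == pytest.approx(10.9, abs=1.0)
    assert q.WF == pytest.approx(3.9, abs=1.0)
    assert q.WMF == pytest.approx(q.WM - q.WF, abs=1e-9)
    assert q.J <= len(m_ann) and q.I <= len(f_ann)
    assert q.L + 101 * len(m_ann) + 41 * len(f_ann) >= record.n_samples - 1
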