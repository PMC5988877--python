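import numpy as np
import pytest

from fetalbss.evaluation import (bland_altman, detection_metrics, match_beats,
                                 mean_of_rows, pool_counts)
from fetalbss.io_formats import AnnotationSet
from fetalbss.qrs import FHRSeries

FS = 1000.0

# Published per-recording fQRS detection counts (TP, FP, FN) and the
# percentages printed alongside them, used as a worked-example oracle.
BENCHMARK_ROWS = [
    ((644, 2, 3), (99.54, 99.69, 99.23, 99.61)),
    ((7933, 91, 143), (98.23, 98.87, 97.13, 98.55)),
    ((10, 0, 0), (100.00, 100.00, 100.00, 100.00)),
]


@pytest.mark.parametrize("counts,expected", BENCHMARK_ROWS)
def test_detection_metrics_worked_examples(counts, expected):
    assert detection_metrics(*counts) == expected


def test_metrics_undefined_cases():
    with pytest.raises(ValueError):
        detection_metrics(0, 5, 0)
    with pytest.raises(ValueError):
        detection_metrics(0, 0, 5)


def test_f1_harmonic_mean_identity():
    rng = np.random.default_rng(0)
    for _ in range(200):
        tp = int(rng.integers(1, 1000))
        fp = int(rng.integers(0, 100))
        fn = int(rng.integers(0, 100))
        se, ppv, _, f1 = detection_metrics(tp, fp, fn, rounded=False)
        assert f1 == pytest.approx(2 * ppv * se / (ppv + se), abs=1e-9)


def test_metric_orderings():
    rng = np.random.default_rng(1)
    for _ in range(200):
        tp = int(rng.integers(1, 500))
        fp = int(rng.integers(0, 200))
        fn = int(rng.integers(0, 200))
        se, ppv, acc, f1 = detection_metrics(tp, fp, fn, rounded=False)
        assert 0 <= min(se, ppv, acc, f1) and max(se, ppv, acc, f1) <= 100
        assert acc <= min(se, ppv) + 1e-12
        assert f1 >= acc - 1e-12


def test_aggregation_modes():
    rows = [(644, 2, 3), (663, 9, 5)]
    pooled = pool_counts(rows)
    assert pooled == detection_metrics(1307, 11, 8)
    per_row = [detection_metrics(*r) for r in rows]
    mean = mean_of_rows(rows)
    for k in range(4):
        assert mean[k] == pytest.approx(
            (per_row[0][k] + per_row[1][k]) / 2, abs=0.0051)


# ---------------------------------------------------------------------------
# beat matching
# ---------------------------------------------------------------------------

def _brute_force_match(det, ref, tol):
    """Exhaustive optimal one-to-one matching cardinality (DFS over all
    assignments of detections to unused in-tolerance references)."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i: int, used: frozenset) -> int:
        if i == len(det):
            return 0
        top = best(i + 1, used)  # leave detection i unmatched
        for j in range(len(ref)):
            if j not in used and abs(det[i] - ref[j]) <= tol:
                top = max(top, 1 + best(i + 1, used | {j}))
        return top

    return best(0, frozenset())


def test_match_identical():
    ann = AnnotationSet(np.arange(0, 5000, 500))
    m = match_beats(ann, ann, 50.0, FS)
    assert (m.TP, m.FP, m.FN) == (10, 0, 0)


def test_match_constant_shift_within_window():
    ref = AnnotationSet(np.arange(1000, 9000, 430))
    det = AnnotationSet(ref.peaks + 30)
    m = match_beats(det, ref, 50.0, FS)
    assert (m.FP, m.FN) == (0, 0)
    assert m.TP == len(ref)


def test_match_spec_instance():
    ref = AnnotationSet([1000, 2000])
    det = AnnotationSet([1000, 1040, 3000])
    m = match_beats(det, ref, 50.0, FS)
    assert (m.TP, m.FP, m.FN) == (1, 2, 1)


def test_negative_tolerance_rejected():
    with pytest.raises(ValueError):
        match_beats(AnnotationSet([1]), AnnotationSet([1]), -1.0, FS)


@pytest.mark.parametrize("seed", range(40))
def test_match_equals_brute_force_optimum(seed):
    rng = np.random.default_rng(seed)
    n_det, n_ref = rng.integers(0, 9), rng.integers(1, 9)
    det = np.unique(rng.integers(0, 2000, n_det))
    ref = np.unique(rng.integers(0, 2000, n_ref))
    tol_ms = float(rng.integers(10, 200))
    m = match_beats(AnnotationSet(det), AnnotationSet(ref), tol_ms, FS)
    assert m.TP == _brute_force_match(det, ref, tol_ms * FS / 1000.0)
    assert m.TP + m.FP == len(det)
    assert m.TP + m.FN == len(ref)


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

def _series(times, bpm):
    bpm = np.asarray(bpm, dtype=float)
    return FHRSeries(beat_times_s=np.asarray(times, dtype=float), bpm=bpm,
                     smoothed_bpm=bpm, maf_window=1)


def test_bland_altman_identical():
    t = np.linspace(1, 60, 120)
    s = _series(t, np.full(120, 140.0))
    rep = bland_altman(s, s)
    assert rep.bias == pytest.approx(0.0)
    assert rep.loa_high - rep.loa_low == pytest.approx(0.0)
    assert rep.pct_within == 100.0


def test_bland_altman_constant_offset():
    t = np.linspace(1, 60, 120)
    a = _series(t, np.full(120, 140.0))
    b = _series(t, np.full(120, 145.0))
    rep = bland_altman(a, b)
    assert rep.bias == pytest.approx(-5.0)
    assert rep.sd == pytest.approx(0.0)


def test_bland_altman_gaussian_coverage():
    rng = np.random.default_rng(99)
    n = 10000
    t = np.arange(n) * 0.43
    base = np.full(n, 140.0)
    d = rng.standard_normal(n)
    rep = bland_altman(_series(t, base + d), _series(t, base))
    assert 94.0 <= rep.pct_within <= 96.0
    assert rep.bias == pytest.approx(0.0, abs=0.05)
    assert rep.sd == pytest.approx(1.0, abs=0.05)


def test_bland_altman_resamples_mismatched_series():
    ta = np.linspace(1, 59, 100)
    tb = np.linspace(0.5, 59.5, 137)
    a = _series(ta, 140 + 5 * np.sin(ta / 5))
    b = _series(tb, 140 + 5 * np.sin(tb / 5))
    rep = bland_altman(a, b)
    assert abs(rep.bias) < 0.2
    assert rep.sd < 0.5


def test_bland_altman_disjoint_series_rejected():
    with pytest.raises(ValueError):
        bland_altman(_series([1, 2, 3], [120, 120, 120]),
                     _series([100, 101], [120, 120]))
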