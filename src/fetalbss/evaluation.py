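"""Beat-to-beat detection statistics and Bland–Altman fHR agreement.

Detections and reference beats are paired one-to-one within a tolerance
window (default ±50 ms, the community convention for fetal QRS scoring)
by an optimal assignment: maximum number of pairs, ties broken by minimum
total |Δt|.  From TP/FP/FN counts,

    Se  = TP/(TP+FN)·100        PPV = TP/(TP+FP)·100
    ACC = TP/(TP+FP+FN)·100     F1  = 2·TP/(2·TP+FP+FN)·100,

reported rounded half-up to two decimals.  True negatives are undefined
for beat detection and never used.

Bland–Altman agreement between two heart-rate series reports the bias
(mean difference), SD of differences and the 95% limits of agreement at
bias ± 1.96 SD, plus the percentage of differences inside those limits.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io_formats import AnnotationSet
from .qrs import FHRSeries

__all__ = ["DetectionMatch", "AgreementReport", "match_beats",
           "detection_metrics", "bland_altman", "pool_counts",
           "mean_of_rows"]

_INFEASIBLE = 1e9


@dataclass
class DetectionMatch:
    TP: int
    FP: int
    FN: int
    pairs: list[tuple[int, int]]   # (detected index, reference index) sample pairs
    tolerance_ms: float


@dataclass
class AgreementReport:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    pct_within: float


def match_beats(detected: AnnotationSet, reference: AnnotationSet,
                tolerance_ms: float, fs: float) -> DetectionMatch:
    """Optimal one-to-one beat pairing within ±tolerance_ms."""
    if tolerance_ms < 0:
        raise ValueError("tolerance must be non-negative")
    det = np.asarray(detected.peaks, dtype=float)
    ref = np.asarray(reference.peaks, dtype=float)
    tol = tolerance_ms * fs / 1000.0
    pairs: list[tuple[int, int]] = []
    if det.size and ref.size:
        dist = np.abs(det[:, None] - ref[None, :])
        cost = np.where(dist <= tol, dist, _INFEASIBLE)
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if dist[i, j] <= tol:
                pairs.append((int(det[i]), int(ref[j])))
    tp = len(pairs)
    return DetectionMatch(TP=tp, FP=int(det.size) - tp, FN=int(ref.size) - tp,
                          pairs=pairs, tolerance_ms=tolerance_ms)


def _round2(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))


def detection_metrics(TP: int, FP: int, FN: int, rounded: bool = True
                      ) -> tuple[float, float, float, float]:
    """(Se, PPV, ACC, F1) in percent, rounded half-up to 2 decimals.

    ``rounded=False`` returns the raw percentages (useful for identity
    checks and further aggregation).
    """
    if TP + FN == 0 or TP + FP == 0:
        raise ValueError("metrics undefined: no reference or no detections")
    se = 100.0 * TP / (TP + FN)
    ppv = 100.0 * TP / (TP + FP)
    acc = 100.0 * TP / (TP + FP + FN)
    f1 = 100.0 * 2 * TP / (2 * TP + FP + FN)
    if not rounded:
        return se, ppv, acc, f1
    return _round2(se), _round2(ppv), _round2(acc), _round2(f1)


def pool_counts(rows: list[tuple[int, int, int]]) -> tuple[float, float, float, float]:
    """Aggregate per-recording counts by summation, then score once."""
    tp = sum(r[0] for r in rows)
    fp = sum(r[1] for r in rows)
    fn = sum(r[2] for r in rows)
    return detection_metrics(tp, fp, fn)


def mean_of_rows(rows: list[tuple[int, int, int]]) -> tuple[float, float, float, float]:
    """Aggregate by averaging the per-recording percentages."""
    per_row = np.array([detection_metrics(*r) for r in rows])
    return tuple(_round2(v) for v in per_row.mean(axis=0))


def bland_altman(fhr_a: FHRSeries, fhr_b: FHRSeries,
                 resample_hz: float = 4.0) -> AgreementReport:
    """Agreement between two heart-rate series.

    Series sharing the same beat times are differenced directly; otherwise
    both are linearly interpolated onto a common uniform time base
    (default 4 Hz) over their overlapping span.
    """
    ta, tb = np.asarray(fhr_a.beat_times_s), np.asarray(fhr_b.beat_times_s)
    va, vb = np.asarray(fhr_a.bpm, float), np.asarray(fhr_b.bpm, float)
    if ta.size == tb.size and np.allclose(ta, tb):
        d = va - vb
    else:
        t0, t1 = max(ta[0], tb[0]), min(ta[-1], tb[-1])
        if t1 <= t0:
            raise ValueError("series do not overlap in time")
        grid = np.arange(t0, t1, 1.0 / resample_hz)
        if grid.size < 2:
            raise ValueError("fewer than 2 common samples after resampling")
        d = np.interp(grid, ta, va) - np.interp(grid, tb, vb)
    if d.size < 2:
        raise ValueError("need at least two differences")
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    within = np.mean((d >= loa_low) & (d <= loa_high)) * 100.0
    return AgreementReport(bias=bias, sd=sd, loa_low=loa_low,
                           loa_high=loa_high, pct_within=float(within))
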