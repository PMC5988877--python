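"""Abdominal-signal quality indices.

An abdominal channel is partitioned into maternal QRS windows (peak
± S_M/2, S_M = 100 ms), fetal QRS windows (± S_F/2, S_F = 40 ms) and the
remaining noise samples.  Average powers of the three portions give the dB
indices

    WM  = 10 log10(PM / PN)   maternal-to-noise,
    WF  = 10 log10(PF / PN)   fetal-to-noise,
    WMF = 10 log10(PM / PF)   maternal-to-fetal,

where PM and PF are in-window mean powers with the noise power PN
subtracted (the signal and the noise are assumed uncorrelated, and P/T-wave
power is neglected).  QRS complexes whose windows overlap a complex of the
other class (feto-maternal coincidence) are excluded from the power
estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import AnnotationSet

__all__ = [
    "QualityIndices",
    "coincidence_filter",
    "noise_power",
    "maternal_power",
    "fetal_power",
    "quality_indices",
    "compute_quality",
]


@dataclass
class QualityIndices:
    PN: float
    PM: float
    PF: float
    WMF: float
    WM: float
    WF: float
    L: int   # noise-sample count
    J: int   # non-overlapping maternal QRS count
    I: int   # non-overlapping fetal QRS count
    S_M_ms: float = 100.0
    S_F_ms: float = 40.0


def _half_width_samples(width_ms: float, fs: float) -> int:
    return int(round(width_ms * fs / 1000.0)) // 2


def coincidence_filter(maternal: AnnotationSet, fetal: AnnotationSet,
                       fs: float) -> tuple[AnnotationSet, AnnotationSet]:
    """Drop QRS complexes whose windows overlap a complex of the other class.

    A maternal peak is kept iff its inclusive window [p - S_M/2, p + S_M/2]
    shares no sample with any fetal window [q - S_F/2, q + S_F/2]; windows
    being inclusive, overlap occurs whenever |p - q| <= (S_M + S_F)/2.
    """
    hm = _half_width_samples(maternal.qrs_width_ms, fs)
    hf = _half_width_samples(fetal.qrs_width_ms, fs)
    sep = hm + hf
    pm, pf = maternal.peaks, fetal.peaks

    def keep(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        if a.size == 0 or b.size == 0:
            return a.copy()
        d = np.min(np.abs(a[:, None] - b[None, :]), axis=1)
        return a[d > sep]

    j_set = AnnotationSet(keep(pm, pf), wave_class=maternal.wave_class,
                          qrs_width_ms=maternal.qrs_width_ms)
    i_set = AnnotationSet(keep(pf, pm), wave_class=fetal.wave_class,
                          qrs_width_ms=fetal.qrs_width_ms)
    return j_set, i_set


def _window_mask(n: int, ann: AnnotationSet, fs: float) -> np.ndarray:
    half = _half_width_samples(ann.qrs_width_ms, fs)
    mask = np.zeros(n, dtype=bool)
    for p in ann.peaks:
        mask[max(0, p - half):min(n, p + half + 1)] = True
    return mask


def noise_power(x: np.ndarray, maternal: AnnotationSet, fetal: AnnotationSet,
                fs: float) -> tuple[float, int]:
    """Mean power over the L samples outside every QRS window (all peaks,
    overlapping or not, shadow the noise region)."""
    x = np.asarray(x, dtype=float)
    mask = _window_mask(x.size, maternal, fs) | _window_mask(x.size, fetal, fs)
    noise = x[~mask]
    if noise.size == 0:
        raise ValueError("QRS windows cover the whole record; no noise samples")
    return float(np.mean(noise ** 2)), int(noise.size)


def _qrs_mean_power(x: np.ndarray, ann: AnnotationSet, fs: float) -> float:
    half = _half_width_samples(ann.qrs_width_ms, fs)
    n = x.size
    total, count = 0.0, 0
    for p in ann.peaks:
        lo, hi = p - half, p + half + 1
        if lo < 0 or hi > n:
            continue
        total += float(np.sum(x[lo:hi] ** 2))
        count += hi - lo
    if count == 0:
        raise ValueError("no usable QRS windows; power undefined")
    return total / count


def maternal_power(x: np.ndarray, j_set: AnnotationSet, PN: float,
                   fs: float) -> float:
    """Mean maternal-QRS power in excess of the noise power (floored at 0)."""
    pm = _qrs_mean_power(np.asarray(x, dtype=float), j_set, fs) - PN
    if pm < 0:
        warnings.warn("noise power exceeds in-window power; PM floored at 0")
        pm = 0.0
    return pm


def fetal_power(x: np.ndarray, i_set: AnnotationSet, PN: float,
                fs: float) -> float:
    pf = _qrs_mean_power(np.asarray(x, dtype=float), i_set, fs) - PN
    if pf < 0:
        warnings.warn("noise power exceeds in-window power; PF floored at 0")
        pf = 0.0
    return pf


def quality_indices(PM: float, PF: float, PN: float) -> tuple[float, float, float]:
    """(WMF, WM, WF) in dB from the three average powers."""
    if PM <= 0 or PF <= 0 or PN <= 0:
        raise ValueError("quality indices undefined for non-positive powers")
    wmf = 10.0 * np.log10(PM / PF)
    wm = 10.0 * np.log10(PM / PN)
    wf = 10.0 * np.log10(PF / PN)
    return float(wmf), float(wm), float(wf)


def compute_quality(x: np.ndarray, maternal: AnnotationSet,
                    fetal: AnnotationSet, fs: float) -> QualityIndices:
    """Full quality report for one abdominal channel."""
    j_set, i_set = coincidence_filter(maternal, fetal, fs)
    PN, L = noise_power(x, maternal, fetal, fs)
    PM = maternal_power(x, j_set, PN, fs)
    PF = fetal_power(x, i_set, PN, fs)
    WMF, WM, WF = quality_indices(PM, PF, PN)
    return QualityIndices(PN=PN, PM=PM, PF=PF, WMF=WMF, WM=WM, WF=WF,
                          L=L, J=len(j_set), I=len(i_set),
                          S_M_ms=maternal.qrs_width_ms,
                          S_F_ms=fetal.qrs_width_ms)
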