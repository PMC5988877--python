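"""R-peak detection (Pan–Tompkins and CWT variants) and fHR series.

Both detectors are deterministic.  The Pan–Tompkins chain is the classic
bandpass → derivative → squaring → moving-window integration → adaptive
double-threshold with search-back, with mode-dependent parameters:
maternal QRS complexes (~100 ms wide, rates 50–110 bpm) use a 5–15 Hz
bandpass, 100 ms integration window and 300 ms refractory period; fetal
complexes (~40 ms, 110–220 bpm) use 10–40 Hz, 40 ms and 200 ms.  Detected
peaks are refined to the local maximum of |bandpassed signal|, so indices
land on the R apex.

The CWT detector builds an energy envelope from Mexican-hat wavelet
coefficients at scales spanning the QRS band and thresholds its local
maxima at median + 7 robust standard deviations (MAD-based; QRS energy
peaks sit far above this on any usable channel, while stationary noise
essentially never crosses it), with the same refractory and
apex-refinement contract.

``fhr_series`` converts R-peak indices into a beat-wise instantaneous heart
rate, bpm_i = 60 fs / RR_i, smoothed by a centered moving average over a
window counted in beats (shrinking at the edges).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps

from .io_formats import AnnotationSet

__all__ = ["FHRSeries", "detect_r_peaks_pt", "detect_r_peaks_cwt", "fhr_series"]

#: Per-mode detector parameters: bandpass (Hz), integration window (ms),
#: refractory period (ms).
MODE_PARAMS = {
    "maternal": {"band": (5.0, 15.0), "integration_ms": 100.0,
                 "refractory_ms": 300.0},
    "fetal": {"band": (10.0, 40.0), "integration_ms": 40.0,
              "refractory_ms": 200.0},
}


@dataclass
class FHRSeries:
    beat_times_s: np.ndarray   # time of the later beat of each RR interval
    bpm: np.ndarray            # instantaneous 60/RR
    smoothed_bpm: np.ndarray   # moving-average filtered
    maf_window: int


def _mode_params(mode: str) -> dict:
    if mode not in MODE_PARAMS:
        raise ValueError(f"unknown detector mode {mode!r}")
    return MODE_PARAMS[mode]


def _bandpassed(signal: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    high = min(band[1], 0.45 * fs)
    sos = sps.butter(3, [band[0], high], btype="band", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, signal)


def _refine_apexes(bp: np.ndarray, rough: np.ndarray, half_window: int,
                   refractory: int) -> np.ndarray:
    """Snap rough detections to the apex of |bp|, then dedupe within the
    refractory period keeping the larger apex."""
    apexes = []
    for p in rough:
        lo = max(0, p - half_window)
        hi = min(bp.size, p + half_window + 1)
        apexes.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    apexes = sorted(set(apexes))
    kept: list[int] = []
    for p in apexes:
        if kept and p - kept[-1] < refractory:
            if np.abs(bp[p]) > np.abs(bp[kept[-1]]):
                kept[-1] = p
        else:
            kept.append(p)
    return np.asarray(kept, dtype=np.int64)


def detect_r_peaks_pt(signal: np.ndarray, fs: float, mode: str = "fetal"
                      ) -> AnnotationSet:
    """Pan–Tompkins style R-peak detection."""
    if fs < 250:
        raise ValueError("detector requires fs >= 250 Hz")
    signal = np.asarray(signal, dtype=float).ravel()
    if signal.size < int(2 * fs):
        raise ValueError("signal shorter than the 2 s learning phase")
    params = _mode_params(mode)
    refractory = int(round(params["refractory_ms"] * fs / 1000.0))
    integ_w = max(1, int(round(params["integration_ms"] * fs / 1000.0)))

    bp = _bandpassed(signal, fs, params["band"])
    deriv = np.convolve(bp, np.array([1, 2, 0, -2, -1]) * (fs / 8.0), "same")
    sq = deriv ** 2
    integ = np.convolve(sq, np.ones(integ_w) / integ_w, "same")
    if not integ.any():
        return AnnotationSet(peaks=np.array([], dtype=np.int64), wave_class=mode)

    candidates, _ = sps.find_peaks(integ, distance=refractory)
    if candidates.size == 0:
        return AnnotationSet(peaks=np.array([], dtype=np.int64), wave_class=mode)

    learn = integ[: int(2 * fs)]
    spki = 0.25 * float(learn.max())
    npki = 0.5 * float(learn.mean())
    accepted: list[int] = []
    rr_history: list[float] = []
    pending: list[int] = []  # rejected candidates, for search-back
    for c in candidates:
        thr = npki + 0.25 * (spki - npki)
        if integ[c] > thr:
            accepted.append(int(c))
            spki = 0.125 * integ[c] + 0.875 * spki
            if len(accepted) > 1:
                rr_history.append(accepted[-1] - accepted[-2])
            pending.clear()
        else:
            npki = 0.125 * integ[c] + 0.875 * npki
            pending.append(int(c))
            # search-back when the expected beat is overdue
            if accepted and rr_history:
                rr_avg = float(np.mean(rr_history[-8:]))
                if c - accepted[-1] > 1.66 * rr_avg:
                    back = [p for p in pending if integ[p] > 0.5 * thr]
                    if back:
                        best = max(back, key=lambda p: integ[p])
                        accepted.append(best)
                        accepted.sort()
                        spki = 0.25 * integ[best] + 0.75 * spki
                        pending.clear()
    peaks = _refine_apexes(bp, np.asarray(accepted, dtype=np.int64),
                           integ_w, refractory)
    return AnnotationSet(peaks=peaks, wave_class=mode)


def detect_r_peaks_cwt(signal: np.ndarray, fs: float, mode: str = "fetal",
                       n_scales: int = 8, threshold_k: float = 7.0
                       ) -> AnnotationSet:
    """R-peak detection from a Mexican-hat CWT energy envelope."""
    if fs < 250:
        raise ValueError("detector requires fs >= 250 Hz")
    signal = np.asarray(signal, dtype=float).ravel()
    if signal.size < int(2 * fs):
        raise ValueError("signal shorter than the 2 s learning phase")
    params = _mode_params(mode)
    refractory = int(round(params["refractory_ms"] * fs / 1000.0))
    half_w = max(1, int(round(params["integration_ms"] * fs / 1000.0)))

    fc = pywt.central_frequency("mexh")
    freqs = np.geomspace(params["band"][0], params["band"][1], n_scales)
    scales = fc * fs / freqs
    coeffs, _ = pywt.cwt(signal, scales, "mexh", sampling_period=1.0 / fs)
    energy = np.mean(np.abs(coeffs), axis=0)
    smooth_w = max(1, int(round(0.02 * fs)))
    energy = np.convolve(energy, np.ones(smooth_w) / smooth_w, "same")
    med = float(np.median(energy))
    mad = float(np.median(np.abs(energy - med)))
    thr = med + threshold_k * 1.4826 * mad
    rough, _ = sps.find_peaks(energy, height=thr, distance=refractory)
    if rough.size == 0:
        return AnnotationSet(peaks=np.array([], dtype=np.int64), wave_class=mode)
    bp = _bandpassed(signal, fs, params["band"])
    peaks = _refine_apexes(bp, rough, half_w, refractory)
    return AnnotationSet(peaks=peaks, wave_class=mode)


def fhr_series(peaks: AnnotationSet, fs: float, maf_window: int = 10) -> FHRSeries:
    """Beat-wise heart rate with centered moving-average smoothing."""
    p = np.asarray(peaks.peaks, dtype=float)
    if p.size < 2:
        raise ValueError("need at least two peaks for an RR interval")
    rr = np.diff(p)
    if np.any(rr <= 0):
        raise ValueError("peak indices must be strictly increasing")
    if maf_window < 1:
        raise ValueError("maf_window must be >= 1")
    bpm = 60.0 * fs / rr
    smoothed = (pd.Series(bpm)
                .rolling(maf_window, center=True, min_periods=1)
                .mean().to_numpy())
    return FHRSeries(beat_times_s=p[1:] / fs, bpm=bpm,
                     smoothed_bpm=smoothed, maf_window=int(maf_window))
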