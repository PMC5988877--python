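"""T/QRS ratio determination (ST-analysis) on an averaged beat.

Fetal T waves are tiny, so the waveform is first averaged over a number of
cardiac cycles (default 30) aligned at the R apex.  On the template:

* QRS amplitude = R-apex value minus the S-trough value (the deepest
  sample within ±60 ms of R),
* T amplitude = template maximum in the T search window (default
  120–350 ms after R, truncated at 80% of the median RR interval) minus a
  local baseline taken as the mean of the isoelectric segment 60–80 ms
  after R,
* T/QRS = T amplitude / QRS amplitude — invariant under any positive
  rescaling of the whole signal, which is what makes it usable on the
  attenuated abdominal extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import AnnotationSet

__all__ = ["BeatAverage", "StanResult", "average_beats", "qrs_amplitude",
           "t_qrs_ratio"]


@dataclass
class BeatAverage:
    template: np.ndarray
    n_beats: int
    pre_ms: float
    post_ms: float
    fs: float

    @property
    def r_index(self) -> int:
        return int(round(self.pre_ms * self.fs / 1000.0))


@dataclass
class StanResult:
    qrs_amplitude: float
    t_amplitude: float
    t_qrs: float
    n_beats: int


def average_beats(signal: np.ndarray, peaks: AnnotationSet, fs: float,
                  n_beats: int = 30,
                  window_ms: tuple[float, float] = (100.0, 400.0)) -> BeatAverage:
    """Mean of the first ``n_beats`` R-aligned beat segments.

    Beats whose window would run past the record bounds are skipped; fewer
    than ``n_beats`` usable beats is an error.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    pre = int(round(window_ms[0] * fs / 1000.0))
    post = int(round(window_ms[1] * fs / 1000.0))
    segments = []
    for p in peaks.peaks:
        if p - pre < 0 or p + post + 1 > signal.size:
            continue
        segments.append(signal[p - pre: p + post + 1])
        if len(segments) == n_beats:
            break
    if len(segments) < n_beats:
        raise ValueError(
            f"only {len(segments)} usable beats, need n_beats={n_beats}")
    return BeatAverage(template=np.mean(segments, axis=0), n_beats=n_beats,
                       pre_ms=window_ms[0], post_ms=window_ms[1], fs=fs)


def qrs_amplitude(template: BeatAverage) -> float:
    """R-apex minus S-trough amplitude on the averaged beat (mV)."""
    t = template.template
    fs = template.fs
    r_idx = template.r_index
    half = int(round(0.02 * fs))
    lo = max(0, r_idx - half)
    r_val = float(t[lo: r_idx + half + 1].max())
    s_half = int(round(0.06 * fs))
    s_lo = max(0, r_idx - s_half)
    s_val = float(t[s_lo: r_idx + s_half + 1].min())
    amp = r_val - s_val
    if amp <= 0:
        raise ValueError("non-positive QRS amplitude on the averaged beat")
    return amp


def t_qrs_ratio(signal: np.ndarray, peaks: AnnotationSet, fs: float,
                n_beats: int = 30,
                t_window_ms: tuple[float, float] = (120.0, 350.0),
                baseline_ms: tuple[float, float] = (60.0, 80.0)) -> StanResult:
    """T/QRS ratio from an averaged beat."""
    rr = np.diff(np.asarray(peaks.peaks, dtype=float))
    post_ms = 400.0
    if rr.size:
        post_ms = min(post_ms, 0.8 * float(np.median(rr)) * 1000.0 / fs)
    t_hi = min(t_window_ms[1], post_ms)
    avg = average_beats(signal, peaks, fs, n_beats=n_beats,
                        window_ms=(100.0, max(post_ms, t_hi)))
    qrs = qrs_amplitude(avg)
    r_idx = avg.r_index
    b_lo = r_idx + int(round(baseline_ms[0] * fs / 1000.0))
    b_hi = r_idx + int(round(baseline_ms[1] * fs / 1000.0)) + 1
    baseline = float(np.mean(avg.template[b_lo:b_hi]))
    w_lo = r_idx + int(round(t_window_ms[0] * fs / 1000.0))
    w_hi = r_idx + int(round(t_hi * fs / 1000.0)) + 1
    if w_hi <= w_lo:
        raise ValueError("T search window is empty at this heart rate")
    t_amp = float(avg.template[w_lo:w_hi].max()) - baseline
    if t_amp <= 0:
        warnings.warn("no positive T deflection found; T amplitude set to 0")
        t_amp = 0.0
    return StanResult(qrs_amplitude=qrs, t_amplitude=t_amp,
                      t_qrs=t_amp / qrs, n_beats=n_beats)
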