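"""Adaptive amplitude/lag compensation and maternal-component subtraction.

Blind source separation hands back a fetal-enhanced component (aECG*) that
still carries maternal residue, and a maternal-dominant component (mECG*).
The two are misaligned in time and scale, so a naive subtraction leaves
large maternal R-wave residuals.  This module:

1. estimates a single integer lag by normalized cross-correlation
   (``estimate_lag``, ties broken toward the smallest |lag|, polarity
   handled separately),
2. fits a slowly varying gain as per-window least squares
   g_w = <a, b> / <b, b> on overlapping windows, linearly interpolated
   between window centers and clipped to ``gain_bounds``
   (``estimate_gain``),
3. subtracts the aligned, scaled maternal estimate from the fetal-enhanced
   component (``compensate_and_subtract``), which is the fECG estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = ["CompensationParams", "estimate_lag", "estimate_gain",
           "compensate_and_subtract"]


@dataclass
class CompensationParams:
    max_lag_ms: float = 50.0
    window_s: float = 2.0
    gain_bounds: tuple[float, float] = (0.0, 10.0)
    min_corr: float = 0.05

    def __post_init__(self) -> None:
        if self.max_lag_ms < 0:
            raise ValueError("max_lag_ms must be non-negative")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")


def estimate_lag(a: np.ndarray, b: np.ndarray, max_lag_ms: float,
                 fs: float) -> int:
    """Integer lag (samples) maximizing |cross-correlation(a, shift(b))|.

    Positive lag means b must be advanced by ``lag`` samples to align with
    a (i.e. b trails a).  Ties go to the smallest |lag|; polarity is left
    to the gain stage.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("signals must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance input; lag undefined")
    max_lag = int(round(max_lag_ms * fs / 1000.0))
    if max_lag < 1:
        raise ValueError("max_lag_ms too small for one sample at this fs")
    ac = a - a.mean()
    bc = b - b.mean()
    # xc[mid + j] = sum_t a[t] b[t - j]; aligning shift is lag = -j
    xc = sps.fftconvolve(ac, bc[::-1])
    mid = a.size - 1
    window = np.abs(xc[mid - max_lag: mid + max_lag + 1])
    lags = -np.arange(-max_lag, max_lag + 1)
    best = window.max()
    # ties (within fp noise) resolved toward the smallest |lag|
    near = np.flatnonzero(window >= best * (1 - 1e-12))
    return int(lags[near[np.argmin(np.abs(lags[near]))]])


def _shift(b: np.ndarray, lag: int) -> np.ndarray:
    """Advance b by ``lag`` samples (b trails a by lag), zero-padding edges."""
    out = np.zeros_like(b)
    if lag == 0:
        return b.copy()
    if lag > 0:
        out[:-lag] = b[lag:]
    else:
        out[-lag:] = b[:lag]
    return out


def estimate_gain(a: np.ndarray, b: np.ndarray, window_s: float, fs: float,
                  gain_bounds: tuple[float, float] = (0.0, 10.0),
                  min_corr: float = 0.0) -> np.ndarray:
    """Per-sample gain series from per-window least squares (50% overlap).

    Windows with <b, b> = 0 carry the previous window's gain (with a
    warning); gains are clipped to ``gain_bounds`` and linearly
    interpolated between window centers.  When ``min_corr`` > 0, windows
    whose normalized correlation |<a,b>| / (||a|| ||b||) falls below it get
    gain 0 — the least-squares estimate there would only fit noise and the
    subtraction would inject, not remove, interference.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.size
    w = max(2, int(round(window_s * fs)))
    step = max(1, w // 2)
    centers, gains = [], []
    for start in range(0, max(1, n - w + 1), step):
        sl = slice(start, min(start + w, n))
        denom = float(b[sl] @ b[sl])
        if denom == 0.0:
            if gains:
                g = gains[-1]
                warnings.warn("degenerate gain window; carrying previous gain")
            else:
                g = np.nan  # resolved by back-fill below
        else:
            num = float(a[sl] @ b[sl])
            norm_a = float(np.sqrt(a[sl] @ a[sl]))
            if min_corr > 0 and norm_a > 0 and \
                    abs(num) / (norm_a * np.sqrt(denom)) < min_corr:
                g = 0.0
            else:
                g = float(np.clip(num / denom, *gain_bounds))
        centers.append((sl.start + sl.stop - 1) / 2.0)
        gains.append(g)
    gains = np.asarray(gains, dtype=float)
    if np.isnan(gains).all():
        warnings.warn("all gain windows degenerate; gain fixed at 0")
        gains = np.zeros_like(gains)
    elif np.isnan(gains).any():
        first = gains[~np.isnan(gains)][0]
        gains[np.isnan(gains)] = first
    return np.interp(np.arange(n), centers, gains)


def compensate_and_subtract(aecg_star: np.ndarray, mecg_star: np.ndarray,
                            params: CompensationParams, fs: float) -> np.ndarray:
    """fECG estimate: aECG* minus the lag-aligned, gain-matched mECG*.

    The polarity of mECG* relative to the maternal content of aECG* is
    taken from the sign of the cross-correlation at the chosen lag, so the
    least-squares gains stay within the (positive) ``gain_bounds``.
    """
    a = np.asarray(aecg_star, dtype=float)
    m = np.asarray(mecg_star, dtype=float)
    lag = estimate_lag(a, m, params.max_lag_ms, fs) if params.max_lag_ms * fs >= 1000 else 0
    m_aligned = _shift(m, lag)
    corr = float((a - a.mean()) @ (m_aligned - m_aligned.mean()))
    if corr < 0:
        m_aligned = -m_aligned
    gain = estimate_gain(a, m_aligned, params.window_s, fs,
                         params.gain_bounds, min_corr=params.min_corr)
    return a - gain * m_aligned
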