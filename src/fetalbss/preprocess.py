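"""Baseline-wander removal and the ICA preprocessing transforms.

The bandpass stage is a linear-phase windowed-sinc FIR (Hamming window,
default band 3–150 Hz) applied forward-backward, so the net group delay is
zero and annotation sample indices stay valid.

Whitening uses the eigenvalue decomposition of the population (1/N)
covariance, C = V D V^T, and maps centered data through V D^{-1/2} V^T so
the channel covariance becomes the identity on the retained subspace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io_formats import MultichannelRecord

__all__ = ["WhiteningResult", "bandpass_filter", "center", "whiten"]

log = logging.getLogger(__name__)


@dataclass
class WhiteningResult:
    xw: np.ndarray          # whitened data (k, N), channel covariance ~ I
    V: np.ndarray           # eigenvectors of the covariance (n, k retained)
    D: np.ndarray           # retained eigenvalues (k,)
    mean: np.ndarray        # per-channel means removed
    K: np.ndarray           # whitening matrix: xw = K @ xc

    @property
    def n_retained(self) -> int:
        return self.xw.shape[0]


def design_bandpass(low_hz: float, high_hz: float, fs: float,
                    order: int | None = None) -> np.ndarray:
    """Hamming windowed-sinc bandpass taps (odd length, type-I linear phase)."""
    if not (0 < low_hz < high_hz < fs / 2):
        raise ValueError(
            f"invalid band edges ({low_hz}, {high_hz}) Hz for fs={fs} Hz")
    if order is None:
        order = int(round(fs))  # ~1 kHz -> 1000 taps+1: ~3 Hz transition
    numtaps = order + 1 if (order + 1) % 2 == 1 else order + 2
    return sps.firwin(numtaps, [low_hz, high_hz], pass_zero=False,
                      window="hamming", fs=fs)


def bandpass_filter(record: MultichannelRecord, low_hz: float = 3.0,
                    high_hz: float = 150.0, order: int | None = None
                    ) -> MultichannelRecord:
    """Zero-phase FIR bandpass of every channel (baseline-wander removal)."""
    taps = design_bandpass(low_hz, high_hz, record.fs, order)
    padlen = min(3 * len(taps), record.n_samples - 1)
    filtered = sps.filtfilt(taps, [1.0], record.signals, axis=1, padlen=padlen)
    return MultichannelRecord(signals=filtered, fs=record.fs,
                              channel_labels=list(record.channel_labels))


def center(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove the per-channel mean: xc = x - E{x}."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] == 0:
        raise ValueError("cannot center an empty signal")
    mean = x.mean(axis=1, keepdims=True)
    return x - mean, mean.ravel()


def whiten(xc: np.ndarray, reduce: bool = False,
           rel_eig_tol: float = 1e-12) -> WhiteningResult:
    """Whiten centered data via eigendecomposition of the 1/N covariance.

    With ``reduce=False`` (default) a rank-deficient covariance — e.g. a
    duplicated or zero-variance channel — raises; with ``reduce=True`` the
    deficient directions (eigenvalue < rel_eig_tol * λmax) are dropped with
    a logged warning and whitening proceeds on the retained subspace.
    """
    xc = np.atleast_2d(np.asarray(xc, dtype=float))
    n, N = xc.shape
    row_scale = np.sqrt(np.mean(xc ** 2, axis=1))
    if np.any(np.abs(xc.mean(axis=1)) > 1e-8 * np.maximum(row_scale, 1e-30)):
        raise ValueError("whiten expects centered input (row means not ~0)")
    variances = np.var(xc, axis=1)
    if np.any(variances == 0):
        bad = int(np.argmin(variances))
        raise np.linalg.LinAlgError(
            f"zero-variance channel {bad}: covariance is singular")
    C = (xc @ xc.T) / N
    eigvals, eigvecs = np.linalg.eigh(C)
    idx = np.argsort(eigvals)[::-1]           # descending
    eigvals, eigvecs = eigvals[idx], eigvecs[:, idx]
    keep = eigvals > rel_eig_tol * eigvals[0]
    if not np.all(keep):
        if not reduce:
            raise np.linalg.LinAlgError(
                "singular covariance (rank "
                f"{int(keep.sum())} < {n}); pass reduce=True to project out "
                "the deficient directions")
        log.warning("dropping %d near-zero-variance direction(s) during "
                    "whitening", int((~keep).sum()))
    V = eigvecs[:, keep]
    D = eigvals[keep]
    K = (V / np.sqrt(D)) @ V.T if keep.all() else (np.diag(1.0 / np.sqrt(D)) @ V.T)
    xw = K @ xc
    return WhiteningResult(xw=xw, V=V, D=D, mean=np.zeros(n), K=K)
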