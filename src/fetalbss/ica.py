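"""Fixed-point independent component analysis and ambiguity resolution.

``fit_ica`` implements the symmetric fixed-point iteration with the
log-cosh contrast on whitened data: every sweep updates all rows of the
unmixing matrix W by

    W_new = E{g(Wx) x^T} - diag(E{g'(Wx)}) W,      g = tanh,

followed by symmetric decorrelation W <- (W W^T)^{-1/2} W.  Convergence is
declared when max_i | |diag(W_new W_old^T)_i| - 1 | < tol.  Rows of W are
orthonormal in whitened space, so the components are uncorrelated with unit
variance; they are defined only up to sign and order.

``resolve_ambiguity`` fixes that indeterminacy for the feto-maternal
problem: each component is classified by the fundamental period of its
energy autocorrelation — maternal-dominant if the implied beat rate falls
in the maternal band (default 50–110 bpm), fetal-enhanced in the fetal band
(default 110–220 bpm), noise otherwise — and its sign is flipped so it
correlates positively with its best-matching reference channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = ["ICAResult", "RoleAssignment", "fit_ica", "resolve_ambiguity"]

log = logging.getLogger(__name__)


@dataclass
class ICAResult:
    W: np.ndarray          # unmixing matrix in the input (whitened) space
    y: np.ndarray          # estimated components, y = W @ x
    A_hat: np.ndarray      # estimated mixing matrix (Moore-Penrose inverse of W)
    n_iter: int
    converged: bool
    seed: int


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    # (W W^T)^{-1/2} W via eigendecomposition of the symmetric Gram matrix
    s, u = np.linalg.eigh(W @ W.T)
    return (u / np.sqrt(s)) @ u.T @ W


def fit_ica(xw: np.ndarray, n_components: int | None = None, seed: int = 0,
            tol: float = 1e-6, max_iter: int = 500) -> ICAResult:
    """Estimate independent components from whitened data (rows = channels)."""
    xw = np.atleast_2d(np.asarray(xw, dtype=float))
    if not np.all(np.isfinite(xw)):
        raise ValueError("non-finite values in ICA input")
    n, N = xw.shape
    if n_components is None:
        n_components = n
    if n_components > n:
        raise ValueError(f"n_components={n_components} exceeds rank {n}")
    rng = np.random.default_rng(seed)
    W = _sym_decorrelate(rng.standard_normal((n_components, n)))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        wx = W @ xw
        g = np.tanh(wx)
        g_prime = 1.0 - g ** 2
        W_new = (g @ xw.T) / N - np.mean(g_prime, axis=1)[:, None] * W
        W_new = _sym_decorrelate(W_new)
        lim = float(np.max(np.abs(np.abs(np.diag(W_new @ W.T)) - 1.0)))
        W = W_new
        if lim < tol:
            converged = True
            break
    if not converged:
        log.warning("ICA did not converge in %d iterations", max_iter)
    y = W @ xw
    return ICAResult(W=W, y=y, A_hat=np.linalg.pinv(W), n_iter=it,
                     converged=converged, seed=seed)


# ---------------------------------------------------------------------------
# Role labeling (sign / order ambiguity resolution)
# ---------------------------------------------------------------------------

@dataclass
class RoleAssignment:
    components: np.ndarray      # sign-corrected components, original count
    roles: list[str]            # per component: maternal | fetal | noise
    scores: list[float]         # beat-periodicity score per component
    rates_bpm: list[float]      # fundamental beat rate per component (nan = none)

    def _pick(self, role: str) -> np.ndarray | None:
        best, best_score = None, -np.inf
        for i, (r, s) in enumerate(zip(self.roles, self.scores)):
            if r == role and s > best_score:
                best, best_score = i, s
        return None if best is None else self.components[best]

    @property
    def maternal(self) -> np.ndarray | None:
        """The maternal-dominant component (highest periodicity score)."""
        return self._pick("maternal")

    @property
    def fetal(self) -> np.ndarray | None:
        """The fetal-enhanced component."""
        return self._pick("fetal")


def _fundamental_period(c: np.ndarray, fs: float, min_bpm: float = 45.0,
                        max_bpm: float = 230.0) -> tuple[float, float]:
    """(rate_bpm, score) from the energy-envelope autocorrelation.

    The fundamental is the smallest-lag autocorrelation peak whose height is
    at least 70% of the strongest peak in the admissible lag range; its
    height is the periodicity score.  Returns (nan, 0) when nothing beats
    a weak-periodicity floor of 0.1.
    """
    e = c.astype(float) ** 2
    e -= e.mean()
    if not e.any():
        return float("nan"), 0.0
    n = e.size
    ac = sps.fftconvolve(e, e[::-1])[n - 1:]
    ac /= ac[0]
    lo = int(fs * 60.0 / max_bpm)
    hi = min(int(fs * 60.0 / min_bpm), n - 1)
    if hi <= lo + 2:
        return float("nan"), 0.0
    seg = ac[lo:hi]
    peaks, props = sps.find_peaks(seg, height=0.1)
    if peaks.size == 0:
        return float("nan"), 0.0
    heights = props["peak_heights"]
    candidates = peaks[heights >= 0.7 * heights.max()]
    fundamental = int(candidates.min())
    score = float(seg[fundamental])
    rate = 60.0 * fs / (fundamental + lo)
    return rate, score


def resolve_ambiguity(y: np.ndarray, reference_channels: np.ndarray, fs: float,
                      maternal_band_bpm: tuple[float, float] = (50.0, 110.0),
                      fetal_band_bpm: tuple[float, float] = (110.0, 220.0),
                      ) -> RoleAssignment:
    """Label components by beat rate and fix their signs.

    Raises ``RuntimeError`` when no component shows detectable beat
    periodicity in either band (nothing to hand downstream).
    """
    y = np.atleast_2d(np.asarray(y, dtype=float)).copy()
    ref = np.atleast_2d(np.asarray(reference_channels, dtype=float))
    roles, scores, rates = [], [], []
    for i in range(y.shape[0]):
        rate, score = _fundamental_period(y[i], fs)
        if np.isnan(rate):
            roles.append("noise")
        elif maternal_band_bpm[0] <= rate < maternal_band_bpm[1]:
            roles.append("maternal")
        elif fetal_band_bpm[0] <= rate <= fetal_band_bpm[1]:
            roles.append("fetal")
        else:
            roles.append("noise")
        scores.append(score)
        rates.append(rate)
        # sign: positive correlation with the best-matching reference channel
        corrs = np.array([np.corrcoef(y[i], r)[0, 1] for r in ref])
        corrs = np.nan_to_num(corrs)
        best = int(np.argmax(np.abs(corrs)))
        sign = np.sign(corrs[best])
        if np.abs(corrs[best]) < 0.05:
            # ambiguous match: fall back to making the spikier tail positive
            sign = np.sign(np.mean(y[i] ** 3)) or 1.0
        if sign < 0:
            y[i] = -y[i]
    if all(r == "noise" for r in roles):
        raise RuntimeError(
            "no component exhibits beat periodicity in the maternal or fetal "
            "band; separation failed")
    return RoleAssignment(components=y, roles=roles, scores=scores,
                          rates_bpm=rates)
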