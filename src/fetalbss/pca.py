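"""Principal-axis estimation, projection and reconstruction.

The principal axes are the eigenvectors of the channel covariance
C = E{x x^T} (population 1/N normalization, computed on centered data):
C u_i = λ_i u_i with λ_1 ≥ λ_2 ≥ … .  Projections s = U^T x are the
principal components; var(s_i) = λ_i, and x = U s reconstructs the data
exactly when all components are kept.  For feto-maternal mixtures the first
principal component is maternal-dominant (the maternal heart carries most
of the abdominal signal power), and the fetal content concentrates in the
axes orthogonal to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PCAResult", "estimate_principal_axes", "project", "reconstruct",
           "variance_probe"]


@dataclass
class PCAResult:
    U: np.ndarray        # orthonormal principal axes, columns u_i
    lambdas: np.ndarray  # eigenvalues, descending
    s: np.ndarray        # principal components, s = U^T x
    C: np.ndarray        # covariance used


def estimate_principal_axes(xc: np.ndarray) -> PCAResult:
    """Eigendecomposition of the covariance of centered data (rows=channels).

    Eigenvalues come back sorted descending; ties are broken by input
    channel order (the order `eigh` returns within a degenerate block).
    Each axis is sign-fixed so its largest-magnitude entry is positive.
    """
    xc = np.atleast_2d(np.asarray(xc, dtype=float))
    n, N = xc.shape
    row_scale = np.sqrt(np.mean(xc ** 2, axis=1)) if N else np.zeros(n)
    if N == 0 or np.any(np.abs(xc.mean(axis=1)) > 1e-8 * np.maximum(row_scale, 1e-30)):
        raise ValueError("estimate_principal_axes expects centered input")
    C = (xc @ xc.T) / N
    eigvals, eigvecs = np.linalg.eigh(C)
    order = np.argsort(eigvals, kind="stable")[::-1]
    lambdas = eigvals[order]
    U = eigvecs[:, order]
    flip = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(n)])
    flip[flip == 0] = 1.0
    U = U * flip
    return PCAResult(U=U, lambdas=lambdas, s=U.T @ xc, C=C)


def project(x: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Principal components s = U^T x."""
    return np.asarray(U).T @ np.atleast_2d(np.asarray(x, dtype=float))


def reconstruct(s: np.ndarray, U: np.ndarray, keep: int | None = None) -> np.ndarray:
    """Rebuild x = U s from the leading ``keep`` components.

    With ``keep = n`` the reconstruction is lossless; with fewer, the mean
    squared reconstruction error equals the sum of the dropped eigenvalues.
    """
    s = np.atleast_2d(np.asarray(s, dtype=float))
    U = np.asarray(U)
    n = U.shape[1]
    if keep is None:
        keep = n
    if not 1 <= keep <= n:
        raise ValueError(f"keep must be in [1, {n}], got {keep}")
    return U[:, :keep] @ s[:keep]


def variance_probe(u: np.ndarray, C: np.ndarray) -> float:
    """ψ(u) = u^T C u for a unit vector u (the variance along u)."""
    u = np.asarray(u, dtype=float).ravel()
    if not np.isclose(np.linalg.norm(u), 1.0, atol=1e-8):
        raise ValueError("variance probe requires a unit vector")
    return float(u @ np.asarray(C) @ u)
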