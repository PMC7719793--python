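"""Matrix primitives underlying the spectral-elastic-net optimizer.

Condensed SVD, nuclear/Frobenius norms, the singular value thresholding
(SVT) proximal operator of the nuclear norm, and a checker for membership
in the nuclear-norm subdifferential.  EEG feature matrices are small and
dense, so everything goes through LAPACK's full SVD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "CondensedSVD",
    "condensed_svd",
    "svt",
    "nuclear_norm",
    "nuclear_subgradient_residual",
]


@dataclass(frozen=True)
class CondensedSVD:
    """Rank-r factorization X = U @ diag(s) @ V.T with orthonormal U, V.

    Only strictly positive singular triplets are kept; ``rank`` may be 0
    for the zero matrix, in which case the factors have zero columns.
    """

    U: np.ndarray  # (p, r), orthonormal columns
    singular_values: np.ndarray  # (r,), positive, non-increasing
    V: np.ndarray  # (q, r), orthonormal columns

    @property
    def rank(self) -> int:
        return self.singular_values.size

    def reconstruct(self) -> np.ndarray:
        return (self.U * self.singular_values) @ self.V.T


def _check_matrix(X: np.ndarray, name: str = "X") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix, got ndim={X.ndim}")
    if not np.all(np.isfinite(X)):
        raise ValueError(f"{name} contains non-finite entries")
    return X


def condensed_svd(X: np.ndarray, rank_tol: float = 1e-12) -> CondensedSVD:
    """Condensed SVD keeping only singular values > rank_tol * sigma_1.

    Parameters
    ----------
    X : (p, q) array
    rank_tol : float
        Relative cutoff defining numerical rank; singular values at or
        below ``rank_tol * sigma_1`` are dropped.
    """
    X = _check_matrix(X)
    if rank_tol < 0:
        raise ValueError("rank_tol must be non-negative")
    U, s, Vt = scipy.linalg.svd(X, full_matrices=False)
    if s.size == 0 or s[0] == 0.0:
        r = 0
    else:
        r = int(np.sum(s > rank_tol * s[0]))
    return CondensedSVD(U=U[:, :r].copy(), singular_values=s[:r].copy(), V=Vt[:r].T.copy())


def svt(X: np.ndarray, tau: float) -> np.ndarray:
    """Singular value thresholding: soft-threshold the spectrum of X by tau.

    This is the proximal operator of ``tau * ||.||_*``: the unique
    minimizer of ``tau*||S||_* + 0.5*||S - X||_F^2``.
    """
    X = _check_matrix(X)
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if tau == 0.0:
        return X.copy()
    U, s, Vt = scipy.linalg.svd(X, full_matrices=False)
    s_shrunk = np.maximum(s - tau, 0.0)
    keep = s_shrunk > 0
    if not np.any(keep):
        return np.zeros_like(X)
    return (U[:, keep] * s_shrunk[keep]) @ Vt[keep]


def nuclear_norm(X: np.ndarray) -> float:
    """Sum of singular values of X."""
    X = _check_matrix(X)
    return float(np.sum(scipy.linalg.svdvals(X)))


def nuclear_subgradient_residual(X: np.ndarray, G: np.ndarray, rank_tol: float = 1e-12) -> float:
    """Distance-like residual of G from the subdifferential of ||X||_*.

    The subdifferential is ``{U V^T + Z : U^T Z = 0, Z V = 0, ||Z||_2 <= 1}``
    with (U, s, V) the condensed SVD of X.  The candidate ``Z`` implied by
    G is ``G - U V^T`` projected onto the orthogonal complement of the
    row/column spaces of X; the residual is the maximum of

    * the leakage of ``G - U V^T`` inside the span (must be 0), and
    * the excess spectral norm ``max(||Z||_2 - 1, 0)`` of the projection.

    Zero (up to tolerance) iff G is a valid subgradient.
    """
    X = _check_matrix(X, "X")
    G = _check_matrix(G, "G")
    if X.shape != G.shape:
        raise ValueError(f"shape mismatch: X {X.shape} vs G {G.shape}")
    f = condensed_svd(X, rank_tol=rank_tol)
    D = G - f.U @ f.V.T
    # split D into span and complement parts: D = P_U D + (I-P_U) D P_V + Z
    P_left = f.U @ (f.U.T @ D)  # rows inside col-space of X
    rest = D - P_left
    P_right = (rest @ f.V) @ f.V.T  # remaining leakage into row-space
    Z = rest - P_right
    leakage = max(
        np.linalg.norm(P_left, ord="fro"),
        np.linalg.norm(P_right, ord="fro"),
    )
    if Z.size == 0 or min(Z.shape) == 0:
        excess = 0.0
    else:
        excess = max(float(scipy.linalg.svdvals(Z)[0]) - 1.0, 0.0)
    return float(max(leakage, excess))
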