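"""Noise-robust moment processing: Cadzow, TLS annihilator, matrix pencil.

In the noiseless case the Toeplitz moment matrix has rank K; noise makes it
full rank.  Cadzow denoising alternates the two projections -- best rank-K
approximation by SVD truncation and re-imposing Toeplitz structure by
diagonal averaging -- to pull the moments back towards the rank-K Toeplitz
set.  The annihilating filter is then found as the total-least-squares
minimiser of ``||S h||`` with ``||h|| = 1``, or the roots are estimated
directly as the rank-reducing numbers of the matrix pencil ``(S0, S1)``
formed by dropping the first/last row of ``S``.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .errors import AnnihilatorNormalizationError, DegeneratePencilError
from .fri_core import MomentVector, moment_toeplitz

__all__ = ["cadzow", "tls_annihilator", "matrix_pencil", "singular_value_ratio"]


def _diagonal_average(M: np.ndarray) -> np.ndarray:
    """Project onto Toeplitz matrices (Frobenius-nearest: average each diagonal).

    Returns the moment vector ``s_0..s_P`` read off the averaged diagonals,
    with ``s`` indexed so that ``M[i, j] ~ s[c + i - j]`` for ``c = ncols - 1``.
    """
    R, C = M.shape
    P = R + C - 2
    s = np.empty(P + 1, dtype=complex)
    c = C - 1
    for q in range(P + 1):
        # entries with c + i - j == q
        vals = [M[i, c + i - q] for i in range(R) if 0 <= c + i - q < C]
        s[q] = np.mean(vals)
    return s


def singular_value_ratio(s: np.ndarray, K: int) -> float:
    """``mu_{K+1} / mu_1`` of the Toeplitz moment matrix (0 if no K+1-th value)."""
    sv = np.linalg.svd(moment_toeplitz(s), compute_uv=False)
    if K >= sv.size or sv[0] == 0.0:
        return 0.0
    return float(sv[K] / sv[0])


def cadzow(moments: MomentVector, K: int, max_iter: int = 20, tol: float = 1e-10) -> MomentVector:
    """Cadzow iterative denoising of the moment vector.

    Alternates SVD truncation to rank K with diagonal averaging on the
    near-square Toeplitz moment matrix, stopping when
    ``mu_{K+1}/mu_1 < tol`` or after ``max_iter`` sweeps.  Noiseless rank-K
    input is a fixed point.
    """
    s = moments.s.copy()
    S = moment_toeplitz(s)
    if K >= min(S.shape):
        raise ValueError("K must be smaller than the smallest moment-matrix dimension")
    for _ in range(max_iter):
        U, sv, Vh = np.linalg.svd(S, full_matrices=False)
        if sv[0] == 0.0 or sv[K] / sv[0] < tol:
            break
        low = (U[:, :K] * sv[:K]) @ Vh[:K]
        s = _diagonal_average(low)
        S = moment_toeplitz(s)
    return MomentVector(s=s, grid=moments.grid, T=moments.T)


def tls_annihilator(moments: MomentVector, K: int) -> np.ndarray:
    """Total-least-squares annihilating filter of length K+1.

    ``h`` is the right singular vector of the Toeplitz system matrix for its
    smallest singular value, normalised so the first element is 1; the
    trailing K entries are then the recurrence coefficients ``h_k``.
    """
    s = moments.s
    P = s.size - 1
    if P + 1 < 2 * K:
        raise ValueError(f"need P+1 >= 2K moments (P={P}, K={K})")
    A = scipy.linalg.toeplitz(s[K:], s[K::-1])  # (P-K+1) x (K+1)
    _, _, Vh = np.linalg.svd(A)
    h = Vh[-1].conj()
    if abs(h[0]) < 1e-10 * np.linalg.norm(h):
        raise AnnihilatorNormalizationError(
            "leading annihilator coefficient is ~0; cannot normalise", h_raw=h
        )
    return h / h[0]


def matrix_pencil(moments: MomentVector, K: int) -> np.ndarray:
    """Roots ``u_k`` as rank-reducing numbers of the moment-matrix pencil.

    ``S0`` (drop first row) and ``S1`` (drop last row) satisfy
    ``rank(S0 - u_k S1) = K - 1``.  For stability the pencil is formed in
    the K-dimensional signal subspace spanned by the K leading left singular
    vectors of the full matrix; the ``u_k`` are the eigenvalues of the
    shift-invariance operator mapping that subspace onto itself.
    """
    S = moment_toeplitz(moments.s)
    if S.shape[0] < K + 1:
        raise DegeneratePencilError(
            f"moment matrix has {S.shape[0]} rows; need at least K+1={K + 1}"
        )
    U, sv, _ = np.linalg.svd(S)
    if K > np.count_nonzero(sv > sv[0] * 1e-13):
        raise DegeneratePencilError("signal subspace is numerically smaller than K")
    Uk = U[:, :K]
    U0 = Uk[1:, :]   # rows 1.. of the subspace basis
    U1 = Uk[:-1, :]  # rows ..-1
    M, _, rank, _ = np.linalg.lstsq(U1, U0, rcond=None)
    if rank < K:
        raise DegeneratePencilError("shift-invariance system is rank deficient")
    return np.linalg.eigvals(M)
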