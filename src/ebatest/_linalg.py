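"""Half-vectorization utilities and normal-theory weight matrices.

The test theory lives in the vech space of symmetric p x p matrices
(dimension p(p+1)/2, lower triangle stacked column-wise).  Everything here
is deliberately dense; the model sizes used by the studies (p <= 100) keep
these matrices comfortably in memory.
"""

from __future__ import annotations

import numpy as np


def vech_indices(p: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices (i >= j) of the lower triangle, column-major.

    The k-th vech element corresponds to entry ``(rows[k], cols[k])``.
    """
    cols, rows = np.triu_indices(p)  # upper triangle row-major == lower col-major
    return rows, cols


def vech(A: np.ndarray) -> np.ndarray:
    r, c = vech_indices(A.shape[0])
    return np.asarray(A)[r, c]


def unvech(v: np.ndarray, p: int) -> np.ndarray:
    A = np.zeros((p, p))
    r, c = vech_indices(p)
    A[r, c] = v
    A[c, r] = v
    return A


def duplication_matrix(p: int) -> np.ndarray:
    """The matrix D_p with D_p vech(A) = vec(A) for symmetric A."""
    if p < 1:
        raise ValueError("p must be a positive integer")
    r, c = vech_indices(p)
    m = r.size
    D = np.zeros((p * p, m))
    k = np.arange(m)
    D[r + c * p, k] = 1.0
    D[c + r * p, k] = 1.0
    return D


def ntml_weight_matrix(sigma_inv: np.ndarray) -> np.ndarray:
    """V = 0.5 * D_p' (Sigma^{-1} kron Sigma^{-1}) D_p without forming the Kronecker.

    Uses V[(ij),(kl)] = m_ij m_kl (A_ik A_jl + A_il A_jk) / 4 with
    multiplicity m = 2 off the diagonal and 1 on it.
    """
    A = sigma_inv
    p = A.shape[0]
    r, c = vech_indices(p)
    mult = np.where(r == c, 1.0, 2.0)
    base = A[np.ix_(r, r)] * A[np.ix_(c, c)] + A[np.ix_(r, c)] * A[np.ix_(c, r)]
    return 0.25 * np.outer(mult, mult) * base


def normal_theory_gamma(sigma: np.ndarray) -> np.ndarray:
    """Asymptotic covariance of vech(S) under normality: 2 D+ (S kron S) D+'.

    Equals the inverse of 2V evaluated at the same covariance; computed
    directly from the same index algebra.
    """
    S = sigma
    p = S.shape[0]
    r, c = vech_indices(p)
    return S[np.ix_(r, r)] * S[np.ix_(c, c)] + S[np.ix_(r, c)] * S[np.ix_(c, r)]
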