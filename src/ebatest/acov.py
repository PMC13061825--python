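"""Asymptotic covariance of sample covariances (Gamma), the residual
weight matrix U, and the eigenvalue weights of U Gamma.

Gamma comes in two flavours behind one interface flag: the moment plug-in
("biased") estimator, and its exact finite-sample unbiased correction
("unbiased", label UG).  Both estimate the covariance of sqrt(n) vech(S).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from ._linalg import ntml_weight_matrix, vech_indices
from .model import FittedModel

GAMMA_VARIANTS = ("biased", "unbiased")


@dataclass
class GammaEstimate:
    """Per-group Gamma matrices plus the joint block-diagonal assembly.

    The joint matrix scales block g by N/N_g so that, paired with the
    N_g/N-weighted V blocks of :func:`u_matrix`, the eigenvalues of
    U Gamma are the weights of the limiting chi-square mixture.
    """

    gamma: list  # per-group symmetric matrices, dim p(p+1)/2
    variant: str
    N: list

    @property
    def joint(self) -> np.ndarray:
        w = np.asarray(self.N, dtype=float) / sum(self.N)
        return sla.block_diag(*[G / wg for G, wg in zip(self.gamma, w)])


def _fourth_moment_ingredients(X: np.ndarray):
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    r, c = vech_indices(p)
    Y = Xc[:, r] * Xc[:, c]  # n x p(p+1)/2 centered cross-products
    m4 = Y.T @ Y / n
    s_b = Y.mean(axis=0)  # biased vech(S)
    return n, p, m4, s_b, Xc


def gamma_adf(X: np.ndarray) -> GammaEstimate:
    """Distribution-free plug-in estimator: m4_ijkl - s_ij s_kl, all
    moments with divisor n."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("at least 2 observations required for gamma_adf")
    n, p, m4, s_b, _ = _fourth_moment_ingredients(X)
    G = m4 - np.outer(s_b, s_b)
    return GammaEstimate(gamma=[0.5 * (G + G.T)], variant="biased", N=[n])


def gamma_unbiased(X: np.ndarray) -> GammaEstimate:
    """Exactly unbiased estimator of Gamma under i.i.d. sampling.

    Built as alpha m4_ijkl + beta s_ij s_kl + gamma (s_ik s_jl + s_il s_jk)
    with m4 the divisor-n central fourth moments, s the unbiased
    covariances, and coefficients

        alpha = n(n^2 - n + 2) / ((n-1)(n-2)(n-3))
        beta  = -(n-1)(n+1) / (n(n-3))
        gamma = -2(n-1)^2 / (n(n-2)(n-3))

    solved from the exact finite-sample expectations of the three
    ingredient statistics (verified unbiased by simulation in the tests).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 6:
        raise ValueError("at least 6 observations required for gamma_unbiased")
    _, p, m4, s_b, Xc = _fourth_moment_ingredients(X)
    r, c = vech_indices(p)
    S = Xc.T @ Xc / (n - 1)  # unbiased covariance matrix
    s_u = S[r, c]
    P = np.outer(s_u, s_u)
    Q = S[np.ix_(r, r)] * S[np.ix_(c, c)] + S[np.ix_(r, c)] * S[np.ix_(c, r)]
    alpha = n * (n**2 - n + 2.0) / ((n - 1.0) * (n - 2.0) * (n - 3.0))
    beta = -(n - 1.0) * (n + 1.0) / (n * (n - 3.0))
    gamma = -2.0 * (n - 1.0) ** 2 / (n * (n - 2.0) * (n - 3.0))
    G = alpha * m4 + beta * P + gamma * Q
    return GammaEstimate(gamma=[0.5 * (G + G.T)], variant="unbiased", N=[n])


def gamma_estimate(X_by_group, variant: str = "biased") -> GammaEstimate:
    """Multi-group Gamma: one block per group, shared variant flag."""
    if variant not in GAMMA_VARIANTS:
        raise ValueError(f"variant must be one of {GAMMA_VARIANTS}")
    est = gamma_adf if variant == "biased" else gamma_unbiased
    parts = [est(X) for X in X_by_group]
    return GammaEstimate(
        gamma=[p.gamma[0] for p in parts], variant=variant, N=[p.N[0] for p in parts]
    )


@dataclass
class UMatrix:
    U: np.ndarray
    V: np.ndarray
    delta: np.ndarray
    rank: int  # expected rank = model df


def joint_v_matrix(fit: FittedModel) -> np.ndarray:
    """Block-diagonal V with group-proportion weights N_g/N, matching the
    weighting of the fit function."""
    w = fit.weights
    blocks = []
    for g, sigma in enumerate(fit.sigma):
        sigma_inv = np.linalg.inv(sigma)
        blocks.append(w[g] * ntml_weight_matrix(sigma_inv))
    return sla.block_diag(*blocks)


def u_matrix(fit: FittedModel) -> UMatrix:
    """U = V - V Delta (Delta' V Delta)^{-1} Delta' V at the NTML solution."""
    if not fit.converged:
        raise ValueError("U matrix requested for a non-converged fit")
    V = joint_v_matrix(fit)
    delta = fit.spec.jacobian(fit.theta)
    VD = V @ delta
    M = delta.T @ VD
    try:
        MinvDV = sla.solve(M, VD.T, assume_a="pos")
    except sla.LinAlgError as err:
        raise ValueError(
            "Delta' V Delta is singular: model not locally identified "
            f"(q={fit.spec.q} parameters)"
        ) from err
    U = V - VD @ MinvDV
    return UMatrix(U=0.5 * (U + U.T), V=V, delta=delta, rank=fit.df)


def eigen_weights(U: np.ndarray, gamma: np.ndarray, d: int, tol: float = 1e-10) -> np.ndarray:
    """The d largest eigenvalues of U Gamma, sorted increasing.

    Solved as the symmetric problem eig(G^{1/2} U G^{1/2}) after projecting
    Gamma onto the PSD cone (numerical dust in the unbiased variant can
    leave tiny negative eigenvalues).  Remaining eigenvalues are checked to
    be numerically zero; negative dust in the kept weights is clipped at 0.
    """
    if d == 0:
        return np.zeros(0)
    gamma = 0.5 * (gamma + gamma.T)
    gv, gw = np.linalg.eigh(gamma)
    gv = np.clip(gv, 0.0, None)
    half = gw * np.sqrt(gv)  # G^{1/2} = W diag(sqrt) W'
    C = half.T @ U @ half
    ev = np.linalg.eigvalsh(0.5 * (C + C.T))
    if d > ev.size:
        raise ValueError("d exceeds matrix dimension")
    top = np.sort(ev)[-d:]
    rest = np.sort(ev)[:-d]
    scale = max(top[-1], 1.0)
    if rest.size and np.max(np.abs(rest)) > 1e-4 * scale:
        raise ValueError(
            "more than d eigenvalues of U Gamma are nonzero; model df and "
            "U/Gamma are inconsistent"
        )
    return np.clip(top, 0.0, None)
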