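"""Confirmatory factor models: specification, implied covariance, ML fit.

A model is a covariance structure Sigma_g(theta) = Lambda_g Phi_g Lambda_g'
+ Psi_g per group g.  Patterns are object arrays whose entries are either a
float (a fixed value) or a string label (a free parameter); using the same
label in several positions -- including across groups -- imposes an
equality constraint, which is how multi-group invariance models are built.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
from scipy.optimize import minimize

from ._linalg import vech_indices


def _as_pattern(x) -> np.ndarray:
    a = np.empty(np.shape(x), dtype=object)
    a[...] = x
    return a


class CfaModelSpec:
    """Single- or multi-group CFA covariance structure.

    Parameters
    ----------
    loadings, factor_cov, residual_cov
        One pattern per group (lists of length G), or a single pattern for
        G = 1.  Symmetric patterns are read from the lower triangle.
    """

    def __init__(self, loadings, factor_cov, residual_cov):
        def listify(x):
            return [x] if isinstance(x, np.ndarray) or np.ndim(x) == 2 else list(x)

        self.loadings = [_as_pattern(m) for m in listify(loadings)]
        self.factor_cov = [_as_pattern(m) for m in listify(factor_cov)]
        self.residual_cov = [_as_pattern(m) for m in listify(residual_cov)]
        if not (len(self.loadings) == len(self.factor_cov) == len(self.residual_cov)):
            raise ValueError("group counts differ between patterns")
        p, l = self.loadings[0].shape
        for L, P, R in zip(self.loadings, self.factor_cov, self.residual_cov):
            if L.shape != (p, l) or P.shape != (l, l) or R.shape != (p, p):
                raise ValueError("pattern shapes inconsistent across groups")
        self.n_vars = p
        self.n_factors = l
        self.n_groups = len(self.loadings)
        self._build_index()

    # -- parameter bookkeeping ------------------------------------------------

    def _build_index(self) -> None:
        index: dict[str, int] = {}
        layouts = []
        for g in range(self.n_groups):
            lay = {}
            for name, M, sym in (
                ("loadings", self.loadings[g], False),
                ("factor_cov", self.factor_cov[g], True),
                ("residual_cov", self.residual_cov[g], True),
            ):
                pos, idx = [], []
                fixed = np.zeros(M.shape)
                nr, nc = M.shape
                for j in range(nc):
                    for i in range(j if sym else 0, nr) if sym else range(nr):
                        e = M[i, j]
                        if isinstance(e, str):
                            if e not in index:
                                index[e] = len(index)
                            pos.append((i, j))
                            idx.append(index[e])
                        else:
                            fixed[i, j] = float(e)
                            if sym:
                                fixed[j, i] = float(e)
                if sym:  # mirror any fixed upper-triangle entries
                    for j in range(nc):
                        for i in range(j):
                            e = M[i, j]
                            if not isinstance(e, str):
                                fixed[i, j] = fixed[j, i] = float(e)
                lay[name] = (
                    np.array([p[0] for p in pos], dtype=int),
                    np.array([p[1] for p in pos], dtype=int),
                    np.array(idx, dtype=int),
                    fixed,
                )
            layouts.append(lay)
        self.parameter_index = index
        self._layouts = layouts

    @property
    def q(self) -> int:
        """Number of distinct free parameters after equality constraints."""
        return len(self.parameter_index)

    @property
    def df(self) -> int:
        """Model degrees of freedom G p(p+1)/2 - q."""
        p = self.n_vars
        d = self.n_groups * p * (p + 1) // 2 - self.q
        if d < 0:
            raise ValueError(f"model under-identified: q={self.q} exceeds moments")
        return d

    @property
    def param_names(self) -> list[str]:
        return sorted(self.parameter_index, key=self.parameter_index.get)

    # -- evaluation -----------------------------------------------------------

    def resolve(self, theta: np.ndarray, group: int):
        """Materialize (Lambda, Phi, Psi) for one group."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.q,):
            raise ValueError(f"theta must have length q={self.q}")
        lay = self._layouts[group]
        out = []
        for name, sym in (("loadings", False), ("factor_cov", True), ("residual_cov", True)):
            r, c, idx, fixed = lay[name]
            M = fixed.copy()
            if r.size:
                M[r, c] = theta[idx]
                if sym:
                    M[c, r] = theta[idx]
            out.append(M)
        return tuple(out)

    def implied_cov(self, theta: np.ndarray, group: int) -> np.ndarray:
        L, P, R = self.resolve(theta, group)
        S = L @ P @ L.T + R
        return 0.5 * (S + S.T)

    def extract_theta(self, matrices_by_group) -> np.ndarray:
        """Inverse of resolve(): read theta off explicit (Lambda, Phi, Psi)."""
        theta = np.full(self.q, np.nan)
        for g, (L, P, R) in enumerate(matrices_by_group):
            lay = self._layouts[g]
            for name, M in (("loadings", L), ("factor_cov", P), ("residual_cov", R)):
                r, c, idx, _ = lay[name]
                for k in range(r.size):
                    val = np.asarray(M)[r[k], c[k]]
                    if not np.isnan(theta[idx[k]]) and abs(theta[idx[k]] - val) > 1e-12:
                        raise ValueError(
                            "inconsistent values for equality-constrained parameter"
                        )
                    theta[idx[k]] = val
        if np.isnan(theta).any():
            raise ValueError("some free parameters not determined by matrices")
        return theta

    def jacobian(self, theta: np.ndarray) -> np.ndarray:
        """Analytic d vech(Sigma_g)/d theta, groups stacked by rows."""
        p, q = self.n_vars, self.q
        r, c = vech_indices(p)
        m = r.size
        delta = np.zeros((self.n_groups * m, q))
        for g in range(self.n_groups):
            L, P, R = self.resolve(theta, g)
            B = L @ P  # p x l
            block = delta[g * m : (g + 1) * m]
            lr, lc, lidx, _ = self._layouts[g]["loadings"]
            for k in range(lr.size):
                i, j = lr[k], lc[k]
                col = np.zeros((p, p))
                col[i, :] += B[:, j]
                col[:, i] += B[:, j]
                block[:, lidx[k]] += col[r, c]
            pr, pc, pidx, _ = self._layouts[g]["factor_cov"]
            for k in range(pr.size):
                i, j = pr[k], pc[k]
                ci, cj = L[:, i], L[:, j]
                if i == j:
                    dS = np.outer(ci, ci)
                else:
                    dS = np.outer(ci, cj) + np.outer(cj, ci)
                block[:, pidx[k]] += dS[r, c]
            rr, rc, ridx, _ = self._layouts[g]["residual_cov"]
            for k in range(rr.size):
                i, j = rr[k], rc[k]
                dS = np.zeros((p, p))
                dS[i, j] += 1.0
                dS[j, i] += 1.0
                if i == j:
                    dS[i, j] = 1.0
                block[:, ridx[k]] += dS[r, c]
        return delta

    def start_values(self, S_list) -> np.ndarray:
        """Default starting values: loadings 0.7, residuals half the sample
        variances, factor variances 1, covariances 0."""
        theta = np.zeros(self.q)
        for g in range(self.n_groups):
            lay = self._layouts[g]
            lr, lc, lidx, _ = lay["loadings"]
            theta[lidx] = 0.7
            pr, pc, pidx, _ = lay["factor_cov"]
            for k in range(pr.size):
                theta[pidx[k]] = 1.0 if pr[k] == pc[k] else 0.0
            rr, rc, ridx, _ = lay["residual_cov"]
            sv = np.diag(np.asarray(S_list[g]))
            for k in range(rr.size):
                theta[ridx[k]] = 0.5 * sv[rr[k]] if rr[k] == rc[k] else 0.0
        return theta


@dataclass
class FittedModel:
    """Converged NTML solution for a (multi-group) CFA."""

    spec: CfaModelSpec
    theta: np.ndarray
    sigma: list  # model-implied covariance per group
    S: list  # biased (divisor N_g) sample covariance per group
    N: list  # per-group sample sizes
    F_min: float
    df: int
    converged: bool
    n_iter: int
    message: str = ""

    @property
    def n_total(self) -> int:
        return int(sum(self.N))

    @property
    def weights(self) -> np.ndarray:
        return np.asarray(self.N, dtype=float) / self.n_total


def ntml_discrepancy(S: np.ndarray, sigma: np.ndarray) -> float:
    """F(S, Sigma) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p."""
    p = S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0 or sign_s <= 0:
        return np.inf
    return float(logdet + np.trace(np.linalg.solve(sigma, S)) - logdet_s - p)


def fit_ntml(
    S_list,
    N_list,
    spec: CfaModelSpec,
    start: np.ndarray | None = None,
    maxiter: int = 500,
    gtol: float = 1e-7,
) -> FittedModel:
    """Minimize the N_g/N-weighted NTML discrepancy with analytic gradient.

    For G = 1 this is exactly the classical single-group fit function.
    Returns ``converged=False`` with diagnostics instead of raising when
    the optimizer stalls.
    """
    S_list = [np.asarray(S, dtype=float) for S in S_list]
    N_list = [int(n) for n in N_list]
    if len(S_list) != spec.n_groups:
        raise ValueError("number of covariance matrices != number of groups")
    p = spec.n_vars
    for S in S_list:
        if S.shape != (p, p):
            raise ValueError("sample covariance has wrong dimension")
        try:
            sla.cholesky(S, lower=True)
        except sla.LinAlgError as err:
            raise ValueError("sample covariance matrix is not positive definite") from err
    N = float(sum(N_list))
    w = np.array(N_list, dtype=float) / N
    logdet_S = [np.linalg.slogdet(S)[1] for S in S_list]

    layouts = spec._layouts

    def value_and_grad(theta):
        F = 0.0
        grad = np.zeros(spec.q)
        for g, S in enumerate(S_list):
            sigma = spec.implied_cov(theta, g)
            try:
                cf = sla.cho_factor(sigma, lower=True)
            except (sla.LinAlgError, ValueError):
                return 1e12, np.zeros(spec.q)
            logdet = 2.0 * np.log(np.diag(cf[0])).sum()
            sigma_inv = sla.cho_solve(cf, np.eye(p))
            F += w[g] * (logdet + (sigma_inv * S).sum() - logdet_S[g] - p)
            # dF/dSigma = Sigma^-1 (Sigma - S) Sigma^-1
            W = sigma_inv @ (sigma - S) @ sigma_inv
            L, P, _ = spec.resolve(theta, g)
            lay = layouts[g]
            lr, lc, lidx, _ = lay["loadings"]
            if lr.size:
                GL = 2.0 * (W @ L @ P)
                np.add.at(grad, lidx, w[g] * GL[lr, lc])
            pr, pc, pidx, _ = lay["factor_cov"]
            if pr.size:
                GP = L.T @ W @ L
                fac = np.where(pr == pc, 1.0, 2.0)
                np.add.at(grad, pidx, w[g] * fac * GP[pr, pc])
            rr, rc, ridx, _ = lay["residual_cov"]
            if rr.size:
                fac = np.where(rr == rc, 1.0, 2.0)
                np.add.at(grad, ridx, w[g] * fac * W[rr, rc])
        return F, grad

    theta0 = spec.start_values(S_list) if start is None else np.asarray(start, float)
    res = minimize(
        value_and_grad,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
    )
    F_min = max(float(res.fun), 0.0)
    grad_ok = np.max(np.abs(res.jac)) < 1e-4  # scale-free stall check
    converged = bool(res.success or grad_ok) and res.fun < 1e11
    sigma = [spec.implied_cov(res.x, g) for g in range(spec.n_groups)]
    return FittedModel(
        spec=spec,
        theta=res.x,
        sigma=sigma,
        S=S_list,
        N=N_list,
        F_min=F_min,
        df=spec.df,
        converged=converged,
        n_iter=int(res.nit),
        message=str(res.message),
    )


def sample_cov(X: np.ndarray) -> np.ndarray:
    """Biased (divisor N) sample covariance of an n x p data matrix."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    return Xc.T @ Xc / X.shape[0]


def fit_data(X_by_group, spec: CfaModelSpec, **kwargs) -> FittedModel:
    """Fit from raw per-group data matrices (biased sample covariances)."""
    S_list = [sample_cov(X) for X in X_by_group]
    N_list = [X.shape[0] for X in X_by_group]
    return fit_ntml(S_list, N_list, spec, **kwargs)


# -- study model builders -----------------------------------------------------


def five_factor_spec(p: int) -> CfaModelSpec:
    """The five-factor goodness-of-fit spec: p/5 indicators per factor,
    loadings free, factor variances fixed at 1, correlations free, diagonal
    residuals free.  q = 2p + 10."""
    if p % 5 != 0:
        raise ValueError("p must be divisible by 5")
    per = p // 5
    L = np.full((p, 5), 0.0, dtype=object)
    for f in range(5):
        for i in range(per):
            L[f * per + i, f] = f"l{f * per + i + 1}"
    P = np.empty((5, 5), dtype=object)
    for i in range(5):
        for j in range(5):
            P[i, j] = 1.0 if i == j else f"phi{min(i, j) + 1}{max(i, j) + 1}"
    R = _diag_free_pattern(p, "psi")
    return CfaModelSpec(L, P, R)


def one_factor_spec(p: int, std_lv: bool = True) -> CfaModelSpec:
    """Single-group one-factor model; ``std_lv`` fixes the factor variance
    at 1 (all loadings free), otherwise the first loading is fixed at 1."""
    L = np.empty((p, 1), dtype=object)
    for i in range(p):
        L[i, 0] = f"l{i + 1}"
    P = np.empty((1, 1), dtype=object)
    P[0, 0] = 1.0 if std_lv else "phi"
    if not std_lv:
        L[0, 0] = 1.0
    R = _diag_free_pattern(p, "psi")
    return CfaModelSpec(L, P, R)


def _diag_free_pattern(p: int, prefix: str, group: str = "") -> np.ndarray:
    R = np.full((p, p), 0.0, dtype=object)
    for i in range(p):
        R[i, i] = f"{prefix}{group}{i + 1}"
    return R


def make_invariance_pair(p: int, G: int):
    """Specs (M0, M1) for weak (metric) invariance testing.

    Both models use marker-variable identification (first loading fixed at
    1, factor variances free per group) so that M0 is exactly M1 plus the
    linear label-merge constraint "loadings equal across groups".  M1 frees
    the p - 1 non-marker loadings per group; M0 shares them.  Degrees of
    freedom satisfy df0 - df1 = (G - 1)(p - 1).
    """
    if p < 3:
        raise ValueError("p >= 3 required for an identified one-factor model")
    if G < 2:
        raise ValueError("invariance testing needs at least two groups")

    def build(shared: bool):
        Ls, Ps, Rs = [], [], []
        for g in range(1, G + 1):
            L = np.empty((p, 1), dtype=object)
            L[0, 0] = 1.0
            for i in range(1, p):
                L[i, 0] = f"l{i + 1}" if shared else f"l{i + 1}.g{g}"
            P = np.empty((1, 1), dtype=object)
            P[0, 0] = f"phi.g{g}"
            Ls.append(L)
            Ps.append(P)
            Rs.append(_diag_free_pattern(p, "psi", f".g{g}."))
        return CfaModelSpec(Ls, Ps, Rs)

    return build(shared=True), build(shared=False)
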