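"""Nested model comparison: the difference statistic T_D = T_0 - T_1 and
eigenvalue-based p values built on the weight matrix U_D.

Two estimators of U_D are provided.  The "2000" method evaluates a single
restricted-projection formula at the M1 estimates only, with the nesting
encoded as linear equality constraints A theta_1 = 0; the "2001" method
takes the difference U_0 - U_1 of the two models' own U matrices at their
own estimates.  The two agree at the population parameter but can differ
substantially in finite samples, which is part of what the procedures
here are designed to expose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
from scipy import stats

from .acov import GammaEstimate, eigen_weights, gamma_estimate, joint_v_matrix, u_matrix
from .gof import TestResult, _label, _parse_method, pvalue_for_method, t_ml, t_rls
from .model import CfaModelSpec, FittedModel


def t_diff(fit0: FittedModel, fit1: FittedModel, base: str = "T_ML") -> float:
    """T_D = T_0 - T_1; warns through the returned value's sign rather
    than flooring when numerically negative."""
    if fit0.df <= fit1.df:
        raise ValueError("M0 must be the more constrained model (df0 > df1)")
    stat = t_ml if base == "T_ML" else t_rls
    return stat(fit0) - stat(fit1)


def constraint_matrix(spec0: CfaModelSpec, spec1: CfaModelSpec) -> np.ndarray:
    """Jacobian A of the linear constraints carrying M1 onto M0.

    Requires M0 to be obtained from M1 purely by merging parameter labels
    (equality constraints) and/or fixing free parameters; every free
    position of M1 must exist in M0's patterns.  Rows are differences
    theta_k - theta_ref for parameters merged in M0 (or unit rows for
    parameters fixed in M0).
    """
    if spec0.n_groups != spec1.n_groups or spec0.n_vars != spec1.n_vars:
        raise ValueError("specs are not comparable")
    q1 = spec1.q
    # map each free M1 parameter to the M0 entry at the same position
    merge: dict = {}
    fixed_rows = []
    mats = ("loadings", "factor_cov", "residual_cov")
    for g in range(spec1.n_groups):
        for name, M1g, M0g in zip(
            mats,
            (spec1.loadings[g], spec1.factor_cov[g], spec1.residual_cov[g]),
            (spec0.loadings[g], spec0.factor_cov[g], spec0.residual_cov[g]),
        ):
            it = np.ndindex(M1g.shape)
            for pos in it:
                e1, e0 = M1g[pos], M0g[pos]
                if isinstance(e1, str):
                    k1 = spec1.parameter_index[e1]
                    if isinstance(e0, str):
                        merge.setdefault(e0, []).append(k1)
                    else:
                        row = np.zeros(q1)
                        row[k1] = 1.0
                        fixed_rows.append(row)
                elif isinstance(e0, str):
                    raise ValueError("M0 frees a parameter fixed in M1: not nested")
    rows = []
    for k_list in merge.values():
        ks = sorted(set(k_list))
        for k in ks[1:]:
            row = np.zeros(q1)
            row[ks[0]] = 1.0
            row[k] = -1.0
            rows.append(row)
    A = np.array(rows + fixed_rows) if (rows or fixed_rows) else np.zeros((0, q1))
    # drop duplicate rows arising from symmetric patterns
    if A.size:
        A = np.unique(A, axis=0)
    if A.shape[0] != spec0.df - spec1.df:
        raise ValueError(
            f"constraint count {A.shape[0]} does not match df0-df1="
            f"{spec0.df - spec1.df}; nesting is not a pure label merge"
        )
    if A.size and np.linalg.matrix_rank(A) < A.shape[0]:
        raise ValueError("constraint Jacobian is rank deficient")
    return A


def u_d_2000(fit1: FittedModel, A: np.ndarray) -> np.ndarray:
    """Restricted-projection U_D from the M1 solution only:

        U_D = V D (D'VD)^-1 A' [A (D'VD)^-1 A']^-1 A (D'VD)^-1 D' V

    with D the M1 Jacobian; U_D Gamma has exactly d0 - d1 positive
    eigenvalues.
    """
    if A.ndim != 2 or A.shape[1] != fit1.spec.q:
        raise ValueError("constraint matrix not conformable with M1 parameters")
    if np.linalg.matrix_rank(A) < A.shape[0]:
        raise ValueError("constraint Jacobian is rank deficient")
    V = joint_v_matrix(fit1)
    D = fit1.spec.jacobian(fit1.theta)
    VD = V @ D
    M = D.T @ VD
    Minv_A = sla.solve(M, A.T, assume_a="pos")  # (D'VD)^-1 A'
    mid = A @ Minv_A  # A (D'VD)^-1 A'
    core = Minv_A @ sla.solve(mid, Minv_A.T, assume_a="pos")
    U_D = VD @ core @ VD.T
    return 0.5 * (U_D + U_D.T)


def u_d_2001(fit0: FittedModel, fit1: FittedModel) -> np.ndarray:
    """U_0 - U_1, each evaluated at its own model's estimates."""
    U0 = u_matrix(fit0).U
    U1 = u_matrix(fit1).U
    return U0 - U1


@dataclass
class NestedComparison:
    """Everything needed to robustly test M0 against M1 on shared data."""

    fit0: FittedModel
    fit1: FittedModel
    gamma: GammaEstimate
    ud_method: str  # "2000" | "2001"
    U_D: np.ndarray
    raw_weights: np.ndarray  # d0 - d1 largest eigenvalues, increasing

    @property
    def d_diff(self) -> int:
        return self.fit0.df - self.fit1.df

    @property
    def trace(self) -> float:
        return float(np.trace(self.U_D @ self.gamma.joint))


def compare_nested(
    fit0: FittedModel,
    fit1: FittedModel,
    X_by_group,
    ud_method: str = "2000",
    gamma_variant: str = "biased",
    gamma: GammaEstimate | None = None,
) -> NestedComparison:
    """Assemble U_D, Gamma and the raw eigenvalue weights for T_D."""
    d_diff = fit0.df - fit1.df
    if d_diff <= 0:
        raise ValueError("M0 must have more degrees of freedom than M1")
    if gamma is None:
        gamma = gamma_estimate(X_by_group, gamma_variant)
    if ud_method == "2000":
        A = constraint_matrix(fit0.spec, fit1.spec)
        U_D = u_d_2000(fit1, A)
    elif ud_method == "2001":
        U_D = u_d_2001(fit0, fit1)
    else:
        raise ValueError("ud_method must be '2000' or '2001'")
    raw = eigen_weights_indefinite(U_D, gamma.joint, d_diff)
    return NestedComparison(fit0, fit1, gamma, ud_method, U_D, raw)


def eigen_weights_indefinite(U_D: np.ndarray, gamma: np.ndarray, d: int) -> np.ndarray:
    """d largest eigenvalues of U_D Gamma.

    Unlike the goodness-of-fit case, U_D from the 2001 method need not be
    PSD in finite samples, so the remaining eigenvalues are not asserted
    to vanish; negative dust in the kept weights is clipped at 0.
    """
    gamma = 0.5 * (gamma + gamma.T)
    gv, gw = np.linalg.eigh(gamma)
    half = gw * np.sqrt(np.clip(gv, 0.0, None))
    C = half.T @ U_D @ half
    ev = np.sort(np.linalg.eigvalsh(0.5 * (C + C.T)))
    return np.clip(ev[-d:], 0.0, None)


def nested_pvalues(
    cmp: NestedComparison,
    methods=("ALL", "pEBA2", "pEBA4", "pEBA6", "pEBAdf", "pOLS2", "SB", "SS", "SF"),
    bases=("T_ML", "T_RLS"),
) -> list[TestResult]:
    """Apply every stabilizer/procedure to T_D and the d0-d1 raw weights.

    SB here uses the eigenvalue-sum scaling (identical to the trace under
    the 2000 method up to numerical precision).
    """
    d = cmp.d_diff
    raw = cmp.raw_weights
    if raw.sum() <= 0:
        raise ValueError("nonpositive eigenvalue sum: degenerate U_D Gamma")
    out = []
    for base in bases:
        T = t_diff(cmp.fit0, cmp.fit1, base)
        flags = "negative T_D" if T < 0 else ""
        for method in methods:
            kind, nb = _parse_method(method)
            if kind in ("pEBA", "EBA") and (nb is None or nb > d):
                out.append(TestResult(
                    _label(method, base, cmp.gamma.variant), method, base,
                    cmp.gamma.variant, T, d, np.nan,
                    flags="skipped: nblocks > df"))
                continue
            stat, p, fl = pvalue_for_method(method, T, raw, d)
            out.append(TestResult(
                _label(method, base, cmp.gamma.variant), method, base,
                cmp.gamma.variant, stat, d, p, flags=(flags + fl)))
    return out


def sb_2001_trace(cmp: NestedComparison, base: str = "T_ML") -> TestResult:
    """The classical difference SB test: c = tr(U_D Gamma)/(d0-d1),
    statistic T_D / c referred to chi-square(d0-d1).

    Defined for the 2001 U_D; the scaled statistic can be negative when
    the trace is, which is reported as-is with a warning flag.
    """
    if cmp.ud_method != "2001":
        raise ValueError("SB_2001 is defined for the 2001 U_D estimator")
    d = cmp.d_diff
    c = cmp.trace / d
    if c == 0:
        raise ValueError("zero trace: degenerate SB_2001 scaling")
    T = t_diff(cmp.fit0, cmp.fit1, base)
    stat = T / c
    flags = "negative scaled statistic" if stat < 0 else ""
    p = float(stats.chi2.sf(stat, d)) if stat >= 0 else 1.0
    return TestResult("SB_2001", "SB_2001", base, cmp.gamma.variant, stat, d, p, flags)
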