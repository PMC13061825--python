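"""Base fit statistics, eigenvalue stabilizers, and robust p values.

The limiting law of both T_ML and T_RLS under a correct model is a
weighted sum of independent chi-square(1) variates whose weights are the
d positive eigenvalues of U Gamma.  Each procedure here differs only in
how it stabilizes the raw eigenvalue estimates before evaluating the tail
probability H(t; weights):

ALL     identity (raw eigenvalues)
SB      every weight replaced by the grand mean (Satorra-Bentler scaling)
EBAx    means of x equally sized blocks of consecutive sorted eigenvalues
pEBAx   elementwise average of the EBAx vector and the grand mean
pEBAdf  pEBA with d singleton blocks: (lambda_i + mean)/2
pOLS2   OLS line of the sorted eigenvalues on their index, fitted values
        averaged with the grand mean, floored at a small positive constant
SS      scale-and-shift of T matched to the chi-square_d mean and variance
SF      scaled F approximation from the first three power sums
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, stats

from .acov import eigen_weights, gamma_estimate, u_matrix
from .model import FittedModel

STABILIZERS = ("ALL", "SB", "EBA", "pEBA", "pEBAdf", "pOLS2")
POLS_FLOOR = 1e-8


@dataclass
class TestResult:
    """One test procedure's outcome."""

    label: str
    procedure: str  # ML | RLS | ALL | pEBAx | pEBAdf | pOLS2 | SB | SS | SF
    base: str  # T_ML | T_RLS
    gamma_variant: str | None  # biased | unbiased | None for normal-theory
    statistic: float
    df: int
    p_value: float
    flags: str = ""


# -- base statistics ----------------------------------------------------------


def t_ml(fit: FittedModel) -> float:
    """(N - 1) times the minimized fit function (total N across groups)."""
    if not fit.converged:
        raise ValueError("test statistic requested for a non-converged fit")
    return (fit.n_total - 1) * fit.F_min


def t_rls(fit: FittedModel) -> float:
    """Reweighted least squares statistic: sum_g N_g/2 tr[(I - Sigma^-1 S)^2]."""
    if not fit.converged:
        raise ValueError("test statistic requested for a non-converged fit")
    total = 0.0
    for sigma, S, n in zip(fit.sigma, fit.S, fit.N):
        A = np.eye(S.shape[0]) - np.linalg.solve(sigma, S)
        total += n / 2.0 * np.trace(A @ A)
    return max(float(total), 0.0)


# -- eigenvalue stabilizers ---------------------------------------------------


def _block_sizes(d: int, nblocks: int) -> np.ndarray:
    """Blocks as equal as possible; the remainder goes to the leading
    blocks, so the larger blocks take the smallest eigenvalues."""
    base, rem = divmod(d, nblocks)
    return np.array([base + 1] * rem + [base] * (nblocks - rem))


def stabilize(raw: np.ndarray, method: str, nblocks: int | None = None) -> np.ndarray:
    """Map raw (sorted increasing) eigenvalues to stabilized weights."""
    lam = np.asarray(raw, dtype=float)
    d = lam.size
    if d < 1:
        raise ValueError("empty eigenvalue vector")
    if np.any(np.diff(lam) < -1e-10):
        raise ValueError("raw eigenvalues must be sorted in increasing order")
    grand = lam.mean()
    if method == "ALL":
        return lam.copy()
    if method == "SB":
        return np.full(d, grand)
    if method in ("EBA", "pEBA"):
        if nblocks is None or nblocks < 1 or nblocks > d:
            raise ValueError("nblocks must be in 1..d for block averaging")
        sizes = _block_sizes(d, nblocks)
        out = np.empty(d)
        start = 0
        for s in sizes:
            out[start : start + s] = lam[start : start + s].mean()
            start += s
        return out if method == "EBA" else 0.5 * (out + grand)
    if method == "pEBAdf":
        return 0.5 * (lam + grand)
    if method == "pOLS2":
        idx = np.arange(1, d + 1, dtype=float)
        if d == 1:
            fitted = lam.copy()
        else:
            slope, intercept = np.polyfit(idx, lam, 1)
            fitted = intercept + slope * idx
        return np.maximum(0.5 * (fitted + grand), POLS_FLOOR)
    raise ValueError(f"unknown stabilizer {method!r}")


# -- weighted chi-square tail probability ------------------------------------


def _ruben_tail(t: float, lam: np.ndarray, tol: float = 1e-9,
                maxterms: int = 20000) -> float:
    """Ruben's expansion: the mixture law as a nonnegative mixture of
    central chi-squares with df d, d+2, ... on the scale of the smallest
    weight.  The truncation error is bounded by the missing mixture mass,
    so the result carries a guaranteed absolute accuracy."""
    d = lam.size
    beta = lam.min()
    ratio = 1.0 - beta / lam  # in [0, 1)
    log_a0 = 0.5 * np.log(beta / lam).sum()
    if log_a0 < -600:
        raise FloatingPointError("leading Ruben coefficient underflows")
    a = [np.exp(log_a0)]
    c = []  # c[r-1] = sum_j ratio_j^r
    power = np.ones(d)
    mass = a[0]
    for k in range(1, maxterms + 1):
        power *= ratio
        c.append(power.sum())
        ak = sum(c[r - 1] * a[k - r] for r in range(1, k + 1)) / (2.0 * k)
        a.append(ak)
        mass += ak
        if 1.0 - mass < tol:
            break
    else:
        raise FloatingPointError("Ruben series did not converge")
    ks = np.arange(len(a))
    cdf = float(np.asarray(a) @ stats.chi2.cdf(t / beta, d + 2 * ks))
    return min(max(1.0 - cdf, 0.0), 1.0)


def _imhof_tail(t: float, lam: np.ndarray, abstol: float = 1e-8) -> float:
    """Imhof-type numerical inversion of the characteristic function."""

    def integrand(u):
        ul = np.multiply.outer(u, lam)
        theta = 0.5 * np.arctan(ul).sum(axis=-1) - 0.5 * t * u
        log_rho = 0.25 * np.log1p(ul**2).sum(axis=-1)
        return np.sin(theta) * np.exp(-log_rho) / u

    # integrand is finite at 0 (limit (sum lam - t)/2) and its envelope
    # decays like u^{-1-d/2}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, err = integrate.quad(
            integrand, 0.0, np.inf, epsabs=abstol, epsrel=0.0, limit=800
        )
    p = 0.5 + val / np.pi
    if not np.isfinite(p) or err > 1e-6:
        raise FloatingPointError("quadrature failed")
    return min(max(p, 0.0), 1.0)


def _mc_tail(t: float, lam: np.ndarray, ndraws: int = 10_000_000, seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, min(ndraws, 2_000_000 // max(lam.size, 1) + 1))
    done = 0
    while done < ndraws:
        m = min(chunk, ndraws - done)
        Z = rng.standard_normal((m, lam.size))
        hits += int(np.count_nonzero((Z * Z) @ lam > t))
        done += m
    return hits / ndraws


def tail_prob_weighted_chisq(t: float, weights: np.ndarray) -> float:
    """P(sum_j w_j Z_j^2 > t) to absolute accuracy ~1e-6.

    Equal weights reduce exactly to a scaled chi-square; otherwise an
    Imhof-type quadrature is used, with a Monte Carlo fallback.
    """
    if t < 0:
        return 1.0
    lam = np.asarray(weights, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("all weights are zero: degenerate distribution")
    if t == 0:
        return 1.0
    if np.ptp(lam) <= 1e-12 * lam[0]:
        return float(stats.chi2.sf(t / lam.mean(), lam.size))
    order = (_ruben_tail, _imhof_tail) if lam.size <= 60 else (_imhof_tail, _ruben_tail)
    for algo in order:
        try:
            return algo(t, lam)
        except Exception:
            continue
    return _mc_tail(t, lam)


# -- p-value procedures -------------------------------------------------------


def pvalue_eigen(
    statistic: float, raw: np.ndarray, method: str, nblocks: int | None = None
) -> float:
    """H(T; stabilized weights).  pEBA with one block is exactly SB."""
    lam = stabilize(np.asarray(raw, dtype=float), method, nblocks)
    return tail_prob_weighted_chisq(statistic, lam)


def pvalue_ss(statistic: float, raw: np.ndarray, d: int) -> tuple[float, float]:
    """Scaled-and-shifted test: T_SS = a T + d - b with a, b from the
    first two power sums of the eigenvalues (the traces of U Gamma and its
    square).  Returns (T_SS, p)."""
    lam = np.asarray(raw, dtype=float)
    s1, s2 = lam.sum(), (lam**2).sum()
    if s2 <= 0:
        raise ValueError("tr((U Gamma)^2) is zero: degenerate SS scaling")
    a = np.sqrt(d / s2)
    b = np.sqrt(d * s1**2 / s2)
    t_ss = a * statistic + d - b
    return float(t_ss), float(stats.chi2.sf(t_ss, d))


def _sf_params(lam: np.ndarray) -> tuple[float, float, float]:
    """Scaled-F parameters (c, df1, df2) by matching the mixture's mean,
    coefficient of variation, and skewness to c F(df1, df2).

    The squared CV and the skewness of an F variate depend only on the two
    degrees of freedom; df2 is found by a 1-D root search and df1, c follow
    in closed form.  When the skewness equation has no admissible root
    (the equal-weight limit df2 -> infinity), a two-moment scaled
    chi-square is returned via df2 = inf.
    """
    s1, s2, s3 = lam.sum(), (lam**2).sum(), (lam**3).sum()
    cv2 = 2.0 * s2 / s1**2
    skew = np.sqrt(8.0) * s3 / s2**1.5

    def df1_of(df2):
        den = cv2 * (df2 - 4.0) - 2.0
        return 2.0 * (df2 - 2.0) / den

    def skew_gap(df2):
        v1 = df1_of(df2)
        if v1 <= 0:
            return np.inf
        g = (2.0 * v1 + df2 - 2.0) * np.sqrt(8.0 * (df2 - 4.0))
        g /= (df2 - 6.0) * np.sqrt(v1 * (v1 + df2 - 2.0))
        return g - skew

    # admissibility: df1 > 0 needs df2 > 4 + 2/cv2; skewness needs df2 > 6
    lo = max(6.0, 4.0 + 2.0 / cv2) + 1e-6
    hi = 1e8
    try:
        if skew_gap(lo) * skew_gap(hi) > 0:
            raise ValueError
        df2 = optimize.brentq(skew_gap, lo, hi, xtol=1e-10, rtol=1e-12)
        df1 = df1_of(df2)
        c = s1 / df1 * (df2 - 2.0) / df2
    except (ValueError, RuntimeError):
        df1 = s1**2 / s2  # Satterthwaite fallback
        df2 = np.inf
        c = s2 / s1
        return c * df1, df1, df2  # scale chosen so T/c ~ chi2(df1) via F limit
    return c * df1, df1, df2


def pvalue_sf(statistic: float, raw: np.ndarray, d: int) -> float:
    """Scaled F-test: T / c ~ F(df1, df2), parameters from the three power
    sums of the raw eigenvalues."""
    lam = np.asarray(raw, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("no positive eigenvalues for the scaled F test")
    scale, df1, df2 = _sf_params(lam)
    if df1 <= 0:
        raise ValueError("scaled F degrees of freedom are not positive")
    x = statistic * df1 / scale  # statistic / c with c = scale/df1
    if np.isinf(df2):
        return float(stats.chi2.sf(x, df1))
    return float(stats.f.sf(x / df1, df1, df2))


# -- the full battery ---------------------------------------------------------

EIGEN_METHODS = ("ALL", "pEBA2", "pEBA4", "pEBA6", "pEBAdf", "pOLS2", "SB")


def _parse_method(name: str) -> tuple[str, int | None]:
    if name.startswith("pEBA") and name != "pEBAdf":
        return "pEBA", int(name[4:])
    if name.startswith("EBA"):
        return "EBA", int(name[3:])
    return name, None


def pvalue_for_method(
    method: str, statistic: float, raw: np.ndarray, d: int
) -> tuple[float, float, str]:
    """Dispatch one procedure; returns (statistic-as-reported, p, flags)."""
    kind, nb = _parse_method(method)
    if kind in ("SS",):
        t_ss, p = pvalue_ss(statistic, raw, d)
        return t_ss, p, ""
    if kind == "SF":
        return statistic, pvalue_sf(statistic, raw, d), ""
    return statistic, pvalue_eigen(statistic, raw, kind, nb), ""


def run_all_tests(
    fit: FittedModel,
    X_by_group,
    methods=None,
    gamma_variants=("biased", "unbiased"),
    bases=("T_ML", "T_RLS"),
) -> list[TestResult]:
    """The normal-theory ML and RLS tests plus every robustified procedure
    crossed with base statistic and Gamma variant (38 results by default).

    pEBAx variants with more blocks than df are skipped with a flag.
    """
    if methods is None:
        methods = EIGEN_METHODS + ("SS", "SF")
    d = fit.df
    stats_by_base = {"T_ML": t_ml(fit), "T_RLS": t_rls(fit)}
    results = [
        TestResult("ML", "ML", "T_ML", None, stats_by_base["T_ML"], d,
                   float(stats.chi2.sf(stats_by_base["T_ML"], d))),
        TestResult("RLS", "RLS", "T_RLS", None, stats_by_base["T_RLS"], d,
                   float(stats.chi2.sf(stats_by_base["T_RLS"], d))),
    ]
    if not methods:
        return results
    U = u_matrix(fit)
    for variant in gamma_variants:
        gam = gamma_estimate(X_by_group, variant)
        raw = eigen_weights(U.U, gam.joint, d)
        for base in bases:
            T = stats_by_base[base]
            for method in methods:
                kind, nb = _parse_method(method)
                if kind in ("pEBA", "EBA") and (nb is None or nb > d):
                    results.append(TestResult(
                        _label(method, base, variant), method, base, variant,
                        T, d, np.nan, flags="skipped: nblocks > df"))
                    continue
                stat, p, flags = pvalue_for_method(method, T, raw, d)
                results.append(TestResult(
                    _label(method, base, variant), method, base, variant,
                    stat, d, p, flags))
    return results


def _label(method: str, base: str, variant: str) -> str:
    lab = method
    if base == "T_RLS":
        lab += "_RLS"
    if variant == "unbiased":
        lab += "_UG"
    return lab
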