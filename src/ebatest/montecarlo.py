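"""Monte Carlo driver: condition grids, replication loops, seeding, and
the rejection-rate aggregation criteria (RMSE, MAD, ARR, B2.5, A7.5).

Seeding is hierarchical: a condition seed spawns one independent
substream per replication via ``numpy.random.SeedSequence``, so results
are bit-identical regardless of execution order or worker count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gof import run_all_tests
from .model import fit_data
from .nested import compare_nested, nested_pvalues, sb_2001_trace
from .simulate import build_study_population

ALPHA = 5.0  # nominal significance level, percent

DISTRIBUTIONS = ("N", "VM1", "IG1", "PL1", "VM2", "IG2", "PL2")


def _family_severity(dist: str) -> tuple[str, str]:
    if dist == "N":
        return "N", "moderate"
    return dist[:-1], {"1": "moderate", "2": "severe"}[dist[-1]]


@dataclass
class Condition:
    study: str  # "1" | "2" | "3gof" | "3inv"
    p: int
    n: int  # per-group sample size
    dist: str  # one of DISTRIBUTIONS
    G: int = 1
    reps: int = 2000
    seed: int = 0
    ud_method: str = "2000"
    h: float = 0.3
    pop_seed: int = 1234  # seed for the drawn population loadings
    lam_method: float | None = None  # method-factor loading override (3gof)

    @property
    def study_tag(self) -> str:
        return {
            "1": "study1",
            "2": "study2",
            "3gof": "study3_gof",
            "3inv": "study3_invariance",
        }[self.study]


@dataclass
class ConditionResult:
    condition: Condition
    rejection_rate: dict  # method label -> percent of p values < 5%
    n_converged: int
    n_discarded: int
    adequacy: bool  # n/q >= 10 for the fitted model
    valid: bool = True  # False when >20% of replications were discarded
    pvalues: dict | None = None


def run_condition(
    cond: Condition,
    methods=None,
    gamma_variants=("biased", "unbiased"),
    keep_pvalues: bool = False,
) -> ConditionResult:
    """Run one simulation condition and return per-method rejection rates.

    Non-converged replications are discarded and counted; rejection rates
    use the converged replications as denominator.
    """
    family, severity = _family_severity(cond.dist)
    pop = build_study_population(cond.study_tag, cond.p, max(cond.G, 2) if
                                 cond.study in ("2", "3inv") else cond.G,
                                 seed=cond.pop_seed, h=cond.h,
                                 lam_method=cond.lam_method)
    seeds = np.random.SeedSequence(cond.seed).spawn(cond.reps)
    pvals: dict[str, list] = {}
    n_conv = n_disc = 0
    q_fitted = None
    for r in range(cond.reps):
        rng = np.random.default_rng(seeds[r])
        try:
            results = _one_replication(
                cond, pop, family, severity, rng, methods, gamma_variants
            )
        except Exception:
            n_disc += 1
            continue
        if results is None:
            n_disc += 1
            continue
        n_conv += 1
        for res in results:
            pvals.setdefault(res.label, []).append(res.p_value)
        if q_fitted is None:
            q_fitted = _fitted_q(cond, pop)
    rr = {
        lab: 100.0 * np.mean(np.asarray(v) < ALPHA / 100.0)
        for lab, v in pvals.items()
    }
    adequacy = bool(q_fitted and cond.n / q_fitted >= 10)
    valid = n_disc <= 0.2 * cond.reps
    return ConditionResult(
        cond, rr, n_conv, n_disc, adequacy, valid,
        pvalues={k: np.asarray(v) for k, v in pvals.items()} if keep_pvalues else None,
    )


def _fitted_q(cond: Condition, pop) -> int:
    # adequacy uses the larger fitted model's parameter count
    if cond.study in ("2", "3inv"):
        return pop.spec_pair[1].q
    return pop.spec.q


def _one_replication(cond, pop, family, severity, rng, methods, gamma_variants):
    from .simulate import draw_sample

    G = len(pop.sigma0)
    X = [draw_sample(family, pop, g, severity, cond.n, rng) for g in range(G)]
    if cond.study in ("1", "3gof"):
        fit = fit_data(X, pop.spec)
        if not fit.converged:
            return None
        return run_all_tests(fit, X, methods=methods, gamma_variants=gamma_variants)
    # nested: fit M0 and M1
    spec0, spec1 = pop.spec_pair
    fit0 = fit_data(X, spec0)
    fit1 = fit_data(X, spec1, start=_warm_start_m1(fit0, spec0, spec1))
    if not (fit0.converged and fit1.converged):
        return None
    out = []
    for variant in gamma_variants:
        cmp = compare_nested(fit0, fit1, X, ud_method=cond.ud_method,
                             gamma_variant=variant)
        out.extend(nested_pvalues(cmp, methods=methods or
                                  ("ALL", "pEBA2", "pEBA4", "pEBA6", "pEBAdf",
                                   "pOLS2", "SB", "SS", "SF")))
        if cond.ud_method == "2001" and variant == "biased":
            out.append(sb_2001_trace(cmp))
    return out


def _warm_start_m1(fit0, spec0, spec1) -> np.ndarray | None:
    """Expand the constrained solution into M1 coordinates as a warm start."""
    if not fit0.converged:
        return None
    try:
        mats = [fit0.spec.resolve(fit0.theta, g) for g in range(spec0.n_groups)]
        return spec1.extract_theta(mats)
    except Exception:
        return None


# -- aggregation criteria -----------------------------------------------------


@dataclass
class AggregateMetrics:
    rmse: float
    mad: float
    arr: float  # percent of conditions with RR in [2.5, 7.5]
    b25: float  # percent below 2.5
    a75: float  # percent above 7.5
    n_conditions: int


def aggregate(rates) -> AggregateMetrics:
    """RMSE/MAD around the 5% nominal rate and the Bradley-band shares.

    Band boundaries are inclusive: RR exactly 2.5 or 7.5 counts as
    acceptable.
    """
    rr = np.asarray(list(rates), dtype=float)
    if rr.size == 0:
        raise ValueError("no rejection rates to aggregate")
    dev = rr - ALPHA
    rmse = float(np.sqrt(np.mean(dev**2)))
    mad = float(np.mean(np.abs(dev)))
    b25 = 100.0 * np.mean(rr < 2.5)
    a75 = 100.0 * np.mean(rr > 7.5)
    arr = 100.0 - b25 - a75
    return AggregateMetrics(rmse, mad, arr, b25, a75, rr.size)


# -- study grids --------------------------------------------------------------

SAMPLE_SIZES = (400, 800, 2000)


def build_study_grid(study: str, scale: str = "full", seed: int = 0,
                     reps: int | None = None) -> list[Condition]:
    """The full study condition grids (84 / 189 / 63 / 189 conditions) or
    a structure-preserving reduced grid for desk-scale runs."""
    if study == "1":
        ps, Gs = (15, 30, 60, 100), (1,)
    elif study == "3gof":
        ps, Gs = (15, 30, 60), (1,)
    elif study in ("2", "3inv"):
        ps, Gs = (5, 10, 20), (2, 4, 8)
    else:
        raise ValueError(f"unknown study {study!r}")
    ns, dists = SAMPLE_SIZES, DISTRIBUTIONS
    default_reps = 2000
    if scale == "reduced":
        ps = ps[:2]
        Gs = Gs[:2] if len(Gs) > 1 else Gs
        ns = (400, 2000)
        dists = ("N", "VM2", "PL1")
        default_reps = 200
    elif scale != "full":
        raise ValueError("scale must be 'full' or 'reduced'")
    reps = default_reps if reps is None else reps
    conds = []
    k = 0
    for p in ps:
        for G in Gs:
            for n in ns:
                for dist in dists:
                    conds.append(Condition(
                        study=study, p=p, n=n, dist=dist, G=G, reps=reps,
                        seed=seed * 1_000_003 + k))
                    k += 1
    return conds
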