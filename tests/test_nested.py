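"""Nested model comparison: T_D, the two U_D estimators, and p values."""

import numpy as np
import pytest
from scipy import stats

import ebatest as e
from ebatest._linalg import normal_theory_gamma
from ebatest.nested import (
    constraint_matrix,
    eigen_weights_indefinite,
    u_d_2000,
    u_d_2001,
)


def _population_fits(pop, N=100000):
    spec0, spec1 = pop.spec_pair
    fit0 = e.fit_ntml(pop.sigma0, [N] * len(pop.sigma0), spec0)
    fit1 = e.fit_ntml(pop.sigma0, [N] * len(pop.sigma0), spec1)
    return fit0, fit1


class TestTDiff:
    def test_arithmetic(self, invariance_pop):
        from ebatest.gof import t_ml
        fit0, fit1 = _population_fits(invariance_pop)
        fit0.F_min, fit1.F_min = 10 / (fit0.n_total - 1), 4 / (fit1.n_total - 1)
        assert e.t_diff(fit0, fit1) == pytest.approx(6.0)

    def test_nesting_order_guard(self, invariance_pop):
        fit0, _ = _population_fits(invariance_pop)
        with pytest.raises(ValueError):
            e.t_diff(fit0, fit0)

    def test_null_mean_matches_chi2_df(self, invariance_pop):
        """Normal data under M0: mean of T_D over replications is near
        q = 4 (3 SEs, 200 reps at n=2000/group)."""
        spec0, spec1 = invariance_pop.spec_pair
        tds = []
        for r in range(200):
            rng = np.random.default_rng(5000 + r)
            X = [e.draw_sample("N", invariance_pop, g, "moderate", 2000, rng)
                 for g in range(2)]
            f0, f1 = e.fit_data(X, spec0), e.fit_data(X, spec1)
            if f0.converged and f1.converged:
                tds.append(e.t_diff(f0, f1))
        tds = np.asarray(tds)
        se = tds.std() / np.sqrt(tds.size)
        assert abs(tds.mean() - 4.0) < 3 * se


class TestConstraintMatrix:
    @pytest.mark.parametrize("p,G", [(5, 2), (5, 4), (10, 2), (10, 8), (20, 4)])
    def test_rank_matches_df_difference(self, p, G):
        s0, s1 = e.make_invariance_pair(p, G)
        A = constraint_matrix(s0, s1)
        assert A.shape == (s0.df - s1.df, s1.q)
        assert np.linalg.matrix_rank(A) == s0.df - s1.df

    def test_constraints_vanish_on_m0_solutions(self, invariance_pop):
        spec0, spec1 = invariance_pop.spec_pair
        fit0, _ = _population_fits(invariance_pop)
        mats = [spec0.resolve(fit0.theta, g) for g in range(2)]
        theta1 = spec1.extract_theta(mats)
        A = constraint_matrix(spec0, spec1)
        assert np.abs(A @ theta1).max() < 1e-8


class TestUDEstimators:
    def test_population_equivalence_2000_2001(self):
        """The two U_D formulas agree at the population parameter for
        every design-grid (p, G) pair."""
        for p, G in [(5, 2), (5, 4), (10, 2), (10, 4)]:
            pop = e.build_study_population("study2", p, G=G, seed=3)
            fit0, fit1 = _population_fits(pop)
            A = constraint_matrix(*pop.spec_pair)
            U2000 = u_d_2000(fit1, A)
            U2001 = u_d_2001(fit0, fit1)
            assert np.abs(U2000 - U2001).max() < 1e-6, (p, G)

    @pytest.mark.parametrize("p,G", [(5, 2), (5, 8), (10, 4), (20, 2)])
    def test_eigenvalue_count(self, p, G):
        """Exactly (G-1)(p-1) eigenvalues of U_D Gamma above tolerance."""
        pop = e.build_study_population("study2", p, G=G, seed=3)
        fit0, fit1 = _population_fits(pop)
        A = constraint_matrix(*pop.spec_pair)
        U_D = u_d_2000(fit1, A)
        w = fit1.weights
        import scipy.linalg as sla
        Gj = sla.block_diag(*[normal_theory_gamma(s) / wg
                              for s, wg in zip(pop.sigma0, w)])
        ev = np.sort(np.real(np.linalg.eigvals(U_D @ Gj)))
        npos = int((ev > 1e-8).sum())
        assert npos == (G - 1) * (p - 1)
        assert np.allclose(ev[-npos:], 1.0, atol=1e-6)

    def test_eigsum_equals_trace_2000(self, invariance_pop, rng):
        spec0, spec1 = invariance_pop.spec_pair
        r = np.random.default_rng(9)
        X = [e.draw_sample("N", invariance_pop, g, "moderate", 400, r)
             for g in range(2)]
        f0, f1 = e.fit_data(X, spec0), e.fit_data(X, spec1)
        cmp = e.compare_nested(f0, f1, X, ud_method="2000")
        assert cmp.raw_weights.sum() == pytest.approx(cmp.trace, rel=1e-8)

    def test_trace_neq_eigsum_2001_finite_sample(self, invariance_pop):
        spec0, spec1 = invariance_pop.spec_pair
        r = np.random.default_rng(17)
        X = [e.draw_sample("VM", invariance_pop, g, "moderate", 400, r)
             for g in range(2)]
        f0, f1 = e.fit_data(X, spec0), e.fit_data(X, spec1)
        cmp = e.compare_nested(f0, f1, X, ud_method="2001")
        assert abs(cmp.raw_weights.sum() - cmp.trace) > 1e-6

    def test_identical_specs_zero_u_d(self, invariance_pop):
        spec0, spec1 = invariance_pop.spec_pair
        r = np.random.default_rng(2)
        X = [e.draw_sample("N", invariance_pop, g, "moderate", 300, r)
             for g in range(2)]
        f1a = e.fit_data(X, spec1)
        f1b = e.fit_data(X, spec1)
        assert np.abs(u_d_2001(f1a, f1b)).max() < 1e-6


@pytest.fixture(scope="module")
def comparison(invariance_pop):
    spec0, spec1 = invariance_pop.spec_pair
    r = np.random.default_rng(23)
    X = [e.draw_sample("N", invariance_pop, g, "moderate", 800, r)
         for g in range(2)]
    f0, f1 = e.fit_data(X, spec0), e.fit_data(X, spec1)
    return e.compare_nested(f0, f1, X, ud_method="2000")


class TestNestedPvalues:
    def test_unit_weights_sb_reduces_to_naive(self, comparison):
        import copy
        cmp = copy.copy(comparison)
        cmp.raw_weights = np.ones(cmp.d_diff)
        res = e.nested_pvalues(cmp, methods=("SB",), bases=("T_ML",))
        T = e.t_diff(cmp.fit0, cmp.fit1)
        assert res[0].p_value == pytest.approx(
            float(stats.chi2.sf(T, cmp.d_diff)), abs=1e-9)

    def test_method_count_full_battery(self, comparison):
        res = e.nested_pvalues(comparison)
        # 9 methods x 2 bases for one Gamma variant; pEBA6 skipped (d=4)
        assert len(res) == 18
        valid = [r for r in res if not np.isnan(r.p_value)]
        assert len(valid) == 16

    def test_sb_2001_hand_example(self, comparison):
        import copy
        cmp = copy.copy(comparison)
        cmp.ud_method = "2001"
        # engineer trace = 8, d_diff = 4 -> c = 2
        cmp.U_D = np.zeros_like(cmp.U_D)
        trace_target = 8.0
        cmp.U_D = (trace_target / np.trace(cmp.gamma.joint)) * np.eye(
            cmp.gamma.joint.shape[0])
        from ebatest.gof import t_ml
        T = e.t_diff(cmp.fit0, cmp.fit1)
        res = e.sb_2001_trace(cmp)
        assert res.statistic == pytest.approx(T / 2.0)
        assert res.p_value == pytest.approx(
            float(stats.chi2.sf(T / 2.0, 4)), abs=1e-10)

    def test_pebadf_weights_arithmetic(self):
        out = e.stabilize(np.array([1.0, 3.0]), "pEBAdf")
        assert out.tolist() == [1.5, 2.5]

    def test_naive_difference_uniform_under_null(self, invariance_pop):
        """KS test of the naive chi-square p values of T_D against uniform
        does not reject at 0.1% (normal data, 300 reps, n=800/group)."""
        spec0, spec1 = invariance_pop.spec_pair
        ps = []
        for r in range(300):
            rng = np.random.default_rng(40000 + r)
            X = [e.draw_sample("N", invariance_pop, g, "moderate", 800, rng)
                 for g in range(2)]
            f0, f1 = e.fit_data(X, spec0), e.fit_data(X, spec1)
            if f0.converged and f1.converged:
                ps.append(float(stats.chi2.sf(e.t_diff(f0, f1), 4)))
        assert stats.kstest(ps, "uniform").pvalue > 0.001
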