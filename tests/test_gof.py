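"""Base statistics, stabilizers, tail probabilities, and the battery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import ebatest as e
from ebatest.gof import (
    _block_sizes,
    _mc_tail,
    _ruben_tail,
    pvalue_for_method,
    t_ml,
    t_rls,
)
from ebatest.model import FittedModel


def _fake_fit(F_min, N, spec=None):
    return FittedModel(spec=spec, theta=None, sigma=[], S=[], N=[N],
                       F_min=F_min, df=10, converged=True, n_iter=1)


class TestBaseStatistics:
    def test_t_ml_perfect_fit(self):
        assert t_ml(_fake_fit(0.0, 500)) == 0.0

    def test_t_ml_arithmetic(self):
        assert t_ml(_fake_fit(0.5, 101)) == pytest.approx(50.0)

    def test_t_rls_scalar(self):
        fit = FittedModel(spec=None, theta=None, sigma=[np.array([[1.0]])],
                          S=[np.array([[2.0]])], N=[10], F_min=0.1, df=0,
                          converged=True, n_iter=1)
        assert t_rls(fit) == pytest.approx(5.0)

    def test_t_rls_perfect_fit(self):
        S = np.array([[2.0, 0.5], [0.5, 1.0]])
        fit = FittedModel(spec=None, theta=None, sigma=[S], S=[S], N=[50],
                          F_min=0.0, df=0, converged=True, n_iter=1)
        assert t_rls(fit) == pytest.approx(0.0, abs=1e-12)

    def test_unconverged_fit_refused(self):
        fit = _fake_fit(0.5, 100)
        fit.converged = False
        with pytest.raises(ValueError):
            t_ml(fit)

    def test_ml_rls_asymptotic_agreement(self, one_factor_pop):
        """The two statistics estimate the same quantity: their relative
        difference is small at large n under a correct model."""
        lam, sigma = one_factor_pop
        spec = e.one_factor_spec(5)
        rel = []
        for r in range(30):
            X = np.random.default_rng(300 + r).multivariate_normal(
                np.zeros(5), sigma, size=20000)
            fit = e.fit_data([X], spec)
            rel.append(abs(t_ml(fit) - t_rls(fit)) / max(t_ml(fit), 1e-12))
        assert np.mean(rel) < 0.05


class TestStabilize:
    def test_sb_grand_mean(self):
        assert e.stabilize(np.array([1.0, 2, 3]), "SB").tolist() == [2, 2, 2]

    def test_peba2_hand_example(self):
        out = e.stabilize(np.array([1.0, 2, 3, 4]), "pEBA", 2)
        assert out.tolist() == [2.0, 2.0, 3.0, 3.0]

    def test_pebadf_hand_example(self):
        out = e.stabilize(np.array([1.0, 3.0]), "pEBAdf")
        assert out.tolist() == [1.5, 2.5]

    def test_pols2_exact_line(self):
        out = e.stabilize(np.array([1.0, 2, 3]), "pOLS2")
        assert np.allclose(out, [1.5, 2.0, 2.5])

    @pytest.mark.parametrize("method,nb", [("ALL", None), ("SB", None),
                                           ("pEBA", 2), ("pEBAdf", None),
                                           ("pOLS2", None), ("EBA", 3)])
    def test_constant_vector_fixed_point(self, method, nb):
        lam = np.full(6, 1.7)
        assert np.allclose(e.stabilize(lam, method, nb), lam)

    def test_unequal_blocks_remainder_leading(self):
        assert _block_sizes(7, 3).tolist() == [3, 2, 2]
        out = e.stabilize(np.arange(1.0, 8.0), "EBA", 3)
        assert np.allclose(out, [2, 2, 2, 4.5, 4.5, 6.5, 6.5])

    def test_invalid_nblocks(self):
        with pytest.raises(ValueError):
            e.stabilize(np.array([1.0, 2.0]), "pEBA", 3)

    @given(st.lists(st.floats(0.01, 50), min_size=2, max_size=40),
           st.integers(1, 6))
    @settings(max_examples=200, deadline=None)
    def test_mean_preservation_and_interpolation(self, lam, nb):
        lam = np.sort(np.asarray(lam))
        nb = min(nb, lam.size)
        grand = lam.mean()
        eba = e.stabilize(lam, "EBA", nb)
        peba = e.stabilize(lam, "pEBA", nb)
        for out in (e.stabilize(lam, "SB"), eba, peba,
                    e.stabilize(lam, "pEBAdf")):
            assert out.mean() == pytest.approx(grand, rel=1e-9)
        # pEBA lies elementwise between EBA and the SB constant
        lo = np.minimum(eba, grand) - 1e-12
        hi = np.maximum(eba, grand) + 1e-12
        assert np.all(peba >= lo) and np.all(peba <= hi)

    def test_pols2_mean_preserved_before_flooring(self, rng):
        lam = np.sort(rng.uniform(0.5, 3.0, 12))
        out = e.stabilize(lam, "pOLS2")
        assert out.mean() == pytest.approx(lam.mean(), rel=1e-9)


class TestTailProbability:
    def test_zero_threshold(self):
        assert e.tail_prob_weighted_chisq(0.0, np.array([1.0, 2.0])) == 1.0

    def test_chi2_quantile(self):
        p = e.tail_prob_weighted_chisq(3.8415, np.array([1.0]))
        assert p == pytest.approx(0.05, abs=1e-4)

    def test_scaling_identity(self):
        p1 = e.tail_prob_weighted_chisq(4.0, np.array([2.0, 2.0]))
        p2 = e.tail_prob_weighted_chisq(2.0, np.array([1.0, 1.0]))
        assert p1 == pytest.approx(p2, abs=1e-9)

    def test_monte_carlo_oracle(self):
        lam = np.array([0.5, 1.0, 2.5])
        p = e.tail_prob_weighted_chisq(4.0, lam)
        phat = _mc_tail(4.0, lam, ndraws=10_000_000, seed=7)
        se = np.sqrt(phat * (1 - phat) / 10_000_000)
        assert abs(p - phat) < 3 * se

    def test_ruben_agrees_with_imhof_large_d(self, rng):
        lam = np.sort(rng.uniform(0.5, 2.0, 80))
        t = lam.sum() * 1.2
        from ebatest.gof import _imhof_tail
        assert _ruben_tail(t, lam) == pytest.approx(_imhof_tail(t, lam), abs=1e-6)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            e.tail_prob_weighted_chisq(1.0, np.zeros(3))

    def test_monotone_in_t(self, rng):
        lam = np.sort(rng.uniform(0.2, 3.0, 10))
        ts = np.linspace(0, 60, 40)
        ps = [e.tail_prob_weighted_chisq(t, lam) for t in ts]
        assert np.all(np.diff(ps) <= 1e-12)


class TestPvalueProcedures:
    def test_peba1_equals_sb(self, rng):
        lam = np.sort(rng.uniform(0.5, 2.0, 8))
        p1 = e.pvalue_eigen(10.0, lam, "pEBA", 1)
        p2 = e.pvalue_eigen(10.0, lam, "SB")
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_sb_is_scaled_chi2(self, rng):
        lam = np.sort(rng.uniform(0.5, 2.0, 6))
        c = lam.mean()
        p = e.pvalue_eigen(9.0, lam, "SB")
        assert p == pytest.approx(stats.chi2.sf(9.0 / c, 6), abs=1e-9)

    def test_all_unit_weights_is_naive_chi2(self):
        p = e.pvalue_eigen(12.0, np.ones(8), "ALL")
        assert p == pytest.approx(stats.chi2.sf(12.0, 8), abs=1e-9)

    def test_ss_identity_reduction(self):
        t_ss, p = e.pvalue_ss(7.0, np.ones(4), 4)
        assert t_ss == pytest.approx(7.0)
        assert p == pytest.approx(stats.chi2.sf(7.0, 4))

    def test_ss_hand_example(self):
        # d=2, sum lam = 4, sum lam^2 = 10 -> a=.44721, b=1.78885
        lam = np.array([(4 - np.sqrt(4)) / 2, (4 + np.sqrt(4)) / 2])  # (1,3)
        assert lam.sum() == 4 and (lam**2).sum() == 10
        t_ss, p = e.pvalue_ss(5.0, lam, 2)
        assert t_ss == pytest.approx(2.4472, abs=1e-4)
        assert p == pytest.approx(0.2942, abs=1e-4)

    def test_sf_equal_weights_matches_scaled_chi2_tail(self):
        """With all weights equal, the mixture is exactly c chi2_d; the
        scaled-F approximation must then be accurate at the 5% tail."""
        c, d = 1.7, 12
        lam = np.full(d, c)
        t = c * stats.chi2.ppf(0.95, d)
        p = e.pvalue_sf(t, lam, d)
        assert p == pytest.approx(0.05, abs=0.01)

    def test_sf_calibration_random_weights(self, rng):
        """SF tail at the mixture's own 95th percentile is close to 5%."""
        lam = np.sort(rng.uniform(0.3, 2.5, 10))
        r = np.random.default_rng(3)
        draws = (r.standard_normal((1_000_000, 10)) ** 2) @ lam
        q95 = np.quantile(draws, 0.95)
        assert 0.03 < e.pvalue_sf(q95, lam, 10) < 0.07

    def test_sf_monotone(self, rng):
        lam = np.sort(rng.uniform(0.3, 2.5, 7))
        ps = [e.pvalue_sf(t, lam, 7) for t in np.linspace(0.5, 40, 25)]
        assert np.all(np.diff(ps) <= 1e-12)


@pytest.fixture(scope="module")
def fit_and_data(study1_pop):
    X = np.random.default_rng(21).multivariate_normal(
        np.zeros(15), study1_pop.sigma0[0], size=1000)
    return e.fit_data([X], study1_pop.spec), [X]


class TestBattery:
    def test_default_count_is_38(self, fit_and_data):
        fit, X = fit_and_data
        res = e.run_all_tests(fit, X)
        assert len(res) == 38
        assert len({r.label for r in res}) == 38

    def test_labels_roundtrip(self, fit_and_data):
        from ebatest.io import split_method_label
        fit, X = fit_and_data
        for r in e.run_all_tests(fit, X):
            name, base, variant = split_method_label(r.label)
            assert name == (r.procedure if r.procedure in
                            ("ML", "RLS", "SB", "SS", "SF", "ALL", "pEBAdf",
                             "pOLS2") else r.label.split("_")[0])
            if r.gamma_variant is not None:
                assert base == r.base
                assert variant == r.gamma_variant

    def test_pvalues_valid(self, fit_and_data):
        fit, X = fit_and_data
        for r in e.run_all_tests(fit, X):
            assert 0.0 <= r.p_value <= 1.0

    def test_near_unit_weights_all_procedures_agree(self, study1_pop):
        """Normal data at n=50000: every robustified p value is within
        0.02 of the naive chi-square p value."""
        X = np.random.default_rng(8).multivariate_normal(
            np.zeros(15), study1_pop.sigma0[0], size=50000)
        fit = e.fit_data([X], study1_pop.spec)
        res = e.run_all_tests(fit, X_by_group=[X])
        by = {r.label: r for r in res}
        for r in res:
            ref = by["ML"] if r.base == "T_ML" else by["RLS"]
            assert abs(r.p_value - ref.p_value) < 0.02, r.label
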