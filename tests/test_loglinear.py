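import numpy as np
import pytest
from scipy import stats

from hiddenpair.loglinear import (
    chi2_pvalue,
    fit_block_independence,
    fit_homogeneous_association,
    fit_partial_independence,
    joint_test,
    marginal_test,
    table_loglik,
)
from hiddenpair.simulate import DiseaseModel, SimConfig, simulate_dataset
from hiddenpair.tables import InvalidInputError, PairTable, build_pair_table

from conftest import ipf_on_margins

UNIFORM = PairTable(np.ones((3, 3, 2), dtype=int), 18)


def y_independent_table(rng):
    """A table where the case and control strata are identical."""
    half = rng.integers(1, 15, size=(3, 3))
    c = np.stack([half, half], axis=-1)
    return PairTable(c, int(c.sum()))


class TestClosedForms:
    def test_block_independence_on_uniform_table(self):
        f = fit_block_independence(UNIFORM)
        assert np.allclose(f.mu, 1.0)

    def test_block_independence_recovers_y_independent_table(self, rng):
        t = y_independent_table(rng)
        f = fit_block_independence(t)
        assert np.allclose(f.mu, t.counts)

    def test_partial_independence_recovers_y_independent_table(self, rng):
        t = y_independent_table(rng)
        for locus in ("p", "q"):
            f = fit_partial_independence(t, locus)
            assert np.allclose(f.mu, t.counts)

    def test_partial_model_exact_fit_has_zero_deviance(self):
        # construct counts satisfying n_ijk = n_ij. n_i.k / n_i.. exactly:
        # Y depends on X_p only
        n_ij = np.array([[8, 4, 4], [6, 6, 4], [4, 4, 4]], dtype=float)
        p_case = np.array([0.25, 0.5, 0.75])  # per X_p level
        c = np.zeros((3, 3, 2))
        c[..., 1] = n_ij * p_case[:, None]
        c[..., 0] = n_ij * (1 - p_case[:, None])
        t = PairTable(c.astype(int), int(c.sum()))
        f = fit_partial_independence(t, "p")
        assert np.allclose(f.mu, t.counts)
        # model holds exactly: zero deviance against the saturated table
        from hiddenpair.loglinear import FittedTable

        saturated = table_loglik(t, FittedTable(t.counts.astype(float), "saturated"))
        assert 2 * (saturated - table_loglik(t, f)) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("locus,axes", [("p", [(2,), (1,)]), ("q", [(2,), (0,)])])
    def test_partial_matches_restricted_ipf(self, rng, random_table_factory, locus, axes):
        for _ in range(10):
            t = random_table_factory(rng)
            f = fit_partial_independence(t, locus)
            oracle = ipf_on_margins(t.counts, axes)
            assert np.abs(f.mu - oracle).max() < 1e-8

    def test_block_matches_restricted_ipf(self, rng, random_table_factory):
        for _ in range(10):
            t = random_table_factory(rng)
            f = fit_block_independence(t)
            oracle = ipf_on_margins(t.counts, [(2,), (0, 1)])
            assert np.abs(f.mu - oracle).max() < 1e-8

    def test_empty_table_rejected(self):
        t = PairTable(np.zeros((3, 3, 2), dtype=int), 0)
        for fn in (fit_block_independence, fit_partial_independence,
                   fit_homogeneous_association, joint_test, marginal_test):
            with pytest.raises(InvalidInputError):
                fn(t)


class TestHomogeneousAssociation:
    def test_uniform_table_converges_immediately(self):
        f = fit_homogeneous_association(UNIFORM)
        assert np.allclose(f.mu, 1.0)
        assert f.converged and f.iterations <= 2

    def test_reduces_to_block_independence_when_it_holds(self, rng):
        # a table that satisfies block independence exactly
        n_ij = rng.integers(1, 6, size=(3, 3))
        c = np.stack([n_ij * 2, n_ij * 3], axis=-1)  # Y split 2:3 in every cell
        t = PairTable(c, int(c.sum()))
        f = fit_homogeneous_association(t, tol=1e-10, max_iter=500)
        fb = fit_block_independence(t)
        assert np.abs(f.mu - fb.mu).max() < 1e-8

    def test_reproduces_all_three_margins(self, rng, random_table_factory):
        for _ in range(20):
            t = random_table_factory(rng)
            f = fit_homogeneous_association(t, tol=1e-10, max_iter=500)
            assert f.converged
            c = t.counts
            assert np.abs(f.mu.sum(axis=2) - c.sum(axis=2)).max() < 1e-8
            assert np.abs(f.mu.sum(axis=1) - c.sum(axis=1)).max() < 1e-8
            assert np.abs(f.mu.sum(axis=0) - c.sum(axis=0)).max() < 1e-8

    def test_zero_margin_cells_frozen_at_zero(self, rng):
        c = rng.integers(1, 10, size=(3, 3, 2))
        c[2, :, :] = 0  # no minor homozygotes at X_p at all
        t = PairTable(c, int(c.sum()))
        f = fit_homogeneous_association(t)
        assert np.all(f.mu[2] == 0.0)
        assert np.all(f.mu[:2] >= 0)

    def test_mass_conservation(self, rng, random_table_factory):
        t = random_table_factory(rng)
        f = fit_homogeneous_association(t, tol=1e-10, max_iter=500)
        assert f.mu.sum() == pytest.approx(t.counts.sum(), rel=1e-10)

    def test_invalid_controls_rejected(self):
        with pytest.raises(ValueError):
            fit_homogeneous_association(UNIFORM, tol=-1.0)
        with pytest.raises(ValueError):
            fit_homogeneous_association(UNIFORM, max_iter=0)


class TestLoglik:
    def test_uniform_value(self):
        f = fit_homogeneous_association(UNIFORM)
        assert table_loglik(UNIFORM, f) == pytest.approx(-18.0)

    def test_observed_fit_is_maximal(self, rng, random_table_factory):
        from hiddenpair.loglinear import FittedTable

        t = random_table_factory(rng)
        saturated = table_loglik(t, FittedTable(t.counts.astype(float), "saturated"))
        for _ in range(20):
            alt = rng.dirichlet(np.ones(18)).reshape(3, 3, 2) * t.counts.sum()
            assert table_loglik(t, FittedTable(alt, "alt")) <= saturated + 1e-9

    def test_zero_fitted_cell_with_observation_is_minus_inf(self):
        from hiddenpair.loglinear import FittedTable

        mu = np.ones((3, 3, 2))
        mu[0, 0, 0] = 0.0
        assert table_loglik(UNIFORM, FittedTable(mu, "alt")) == -np.inf

    def test_deviance_identity(self, rng, random_table_factory):
        # 2*(L_MH - L_MB) equals the difference of G^2 vs the saturated table
        t = random_table_factory(rng)
        fh = fit_homogeneous_association(t, tol=1e-12, max_iter=1000)
        fb = fit_block_independence(t)
        direct = 2 * (table_loglik(t, fh) - table_loglik(t, fb))
        c = t.counts.astype(float)
        g2 = lambda mu: 2 * np.sum(np.where(c > 0, c * np.log(np.where(c > 0, c, 1) / mu), 0))
        assert direct == pytest.approx(g2(fb.mu) - g2(fh.mu), abs=1e-6)
        assert joint_test(t, tol=1e-12, max_iter=1000).stat == pytest.approx(direct, abs=1e-6)


class TestTests:
    def test_exact_null_gives_zero_statistics(self, rng):
        t = y_independent_table(rng)
        jt = joint_test(t)
        assert jt.stat == pytest.approx(0.0, abs=1e-9)
        assert jt.p_raw == pytest.approx(1.0)
        for locus in ("p", "q"):
            assert marginal_test(t, locus).stat == pytest.approx(0.0, abs=1e-9)

    def test_nesting_monotonicity(self, rng, random_table_factory):
        for _ in range(30):
            t = random_table_factory(rng)
            lb = table_loglik(t, fit_block_independence(t))
            lp = table_loglik(t, fit_partial_independence(t, "p"))
            lh = table_loglik(t, fit_homogeneous_association(t, tol=1e-10, max_iter=500))
            assert lb <= lp + 1e-9
            assert lp <= lh + 1e-9

    def test_marginal_equals_collapsed_single_snp_g2(self, rng, random_table_factory):
        t = random_table_factory(rng)
        collapsed = t.counts.sum(axis=1)  # 3x2 of X_p vs Y
        row = collapsed.sum(axis=1, keepdims=True)
        col = collapsed.sum(axis=0, keepdims=True)
        expected = row * col / collapsed.sum()
        g2 = 2 * np.sum(collapsed * np.log(collapsed / expected))
        assert marginal_test(t, "p").stat == pytest.approx(g2, abs=1e-9)

    def test_joint_default_df_is_four_and_override(self, rng, random_table_factory):
        t = random_table_factory(rng)
        jt4 = joint_test(t)
        jt2 = joint_test(t, df=2)
        assert jt4.df == 4 and jt2.df == 2
        assert jt4.stat == pytest.approx(jt2.stat)
        assert jt2.p_raw <= jt4.p_raw  # same stat, fewer df

    def test_null_statistics_follow_chi_square(self):
        """Joint statistics from no-association data behave like chi2(4)."""
        model = DiseaseModel(alpha=1 / 9, theta=1.0)
        cfg = SimConfig(model, n_cases=250, n_controls=250, n_null_snps=0, seed=99)
        stats_ = []
        for r in range(300):
            G, y, _ = simulate_dataset(cfg, r)
            t = build_pair_table(G.values[:, 0], G.values[:, 1], y)
            stats_.append(joint_test(t).stat)
        ks = stats.kstest(stats_, stats.chi2(4).cdf)
        assert ks.pvalue > 1e-3


class TestChi2Pvalue:
    def test_zero_statistic(self):
        assert chi2_pvalue(0.0, 2) == pytest.approx(1.0)

    def test_critical_value(self):
        assert chi2_pvalue(5.991, 2) == pytest.approx(0.05, abs=1e-4)

    def test_closed_form_for_two_df(self, rng):
        for x in rng.uniform(0, 20, size=10):
            assert chi2_pvalue(x, 2) == pytest.approx(np.exp(-x / 2), rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            chi2_pvalue(-0.1, 2)
        with pytest.raises(InvalidInputError):
            chi2_pvalue(1.0, 0)
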