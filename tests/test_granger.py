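import numpy as np
import pytest

from sdaeconn import (ConditionalGC, conditional_gc, connectivity_graph,
                      fit_var, prewhiten, select_order, significance)


def simulate_var(coefs, n, sd=1.0, seed=0, burn=200):
    """Simulate a VAR with coefficient array (k, k, p)."""
    rng = np.random.default_rng(seed)
    k, _, p = coefs.shape
    x = np.zeros((k, n + burn))
    for t in range(p, n + burn):
        for j in range(1, p + 1):
            x[:, t] += coefs[:, :, j - 1] @ x[:, t - j]
        x[:, t] += sd * rng.standard_normal(k)
    return x[:, burn:]


@pytest.fixture(scope="module")
def bivariate_coupled():
    """y depends on x with lag 1, coefficient 0.8; x is AR(1)."""
    coefs = np.zeros((2, 2, 1))
    coefs[0, 0, 0] = 0.5    # x own lag
    coefs[1, 0, 0] = 0.8    # x -> y
    coefs[1, 1, 0] = 0.2    # y own lag
    return simulate_var(coefs, 5000, seed=1)


class TestFitVar:
    def test_white_noise_coefficients_near_zero(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((3, 8000))
        model = fit_var(x, p=2)
        # asymptotic se of a VAR coefficient on white noise ~ 1/sqrt(N)
        assert np.abs(model.coefs).max() < 3.0 / np.sqrt(8000)

    def test_recovers_known_var1(self):
        coefs = np.zeros((2, 2, 1))
        coefs[0, 0, 0] = 0.5
        coefs[1, 0, 0] = 0.5
        coefs[1, 1, 0] = 0.3
        x = simulate_var(coefs, 5000, seed=3)
        model = fit_var(x, p=1)
        np.testing.assert_allclose(model.coefs[:, :, 0], coefs[:, :, 0],
                                   atol=0.05)

    def test_residual_covariance_consistency(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((3, 2000))
        model = fit_var(x, p=2)
        expect = model.residuals @ model.residuals.T / model.residuals.shape[1]
        np.testing.assert_allclose(model.Sigma, expect, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(model.Sigma) > -1e-10)

    def test_matches_statsmodels(self):
        """Independent cross-check against the statsmodels VAR fit."""
        from statsmodels.tsa.api import VAR

        coefs = np.zeros((2, 2, 2))
        coefs[0, 0, 0] = 0.4
        coefs[1, 0, 1] = 0.3
        coefs[1, 1, 0] = 0.25
        x = simulate_var(coefs, 3000, seed=5)
        ours = fit_var(x, p=2)
        theirs = VAR(x.T).fit(maxlags=2, trend="c")
        np.testing.assert_allclose(
            np.stack([ours.coefs[:, :, j] for j in range(2)]),
            theirs.coefs, atol=1e-8)
        np.testing.assert_allclose(ours.intercept, theirs.intercept,
                                   atol=1e-8)

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_var(np.zeros((4, 20)), p=10)

    def test_collinear_series_rejected(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal(500)
        with pytest.raises(np.linalg.LinAlgError):
            fit_var(np.vstack([a, a]), p=2)


class TestSelectOrder:
    def test_recovers_var2(self):
        coefs = np.zeros((2, 2, 2))
        coefs[0, 0, 0] = 0.3
        coefs[0, 1, 1] = -0.4
        coefs[1, 1, 0] = 0.3
        coefs[1, 0, 1] = 0.4
        x = simulate_var(coefs, 5000, seed=7)
        p, table = select_order(x, p_max=8)
        assert p == 2
        assert {"aic", "bic", "aic_bic_ratio"} <= set(table.columns)

    def test_white_noise_prefers_order_one(self):
        hits = 0
        for seed in range(10):
            x = np.random.default_rng(seed).standard_normal((2, 2000))
            p, _ = select_order(x, p_max=6)
            hits += (p == 1)
        assert hits >= 9

    def test_pmax_one_returns_one(self):
        x = np.random.default_rng(8).standard_normal((2, 500))
        assert select_order(x, p_max=1)[0] == 1


class TestConditionalGc:
    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((3, 5000))
        for (s, t) in [(0, 1), (1, 2), (2, 0)]:
            f = conditional_gc(x, target=t, source=s, p=2)
            assert 0.0 <= f <= 0.01

    def test_directed_coupling_detected(self, bivariate_coupled):
        f_fwd = conditional_gc(bivariate_coupled, target=1, source=0, p=1)
        f_rev = conditional_gc(bivariate_coupled, target=0, source=1, p=1)
        assert f_fwd > 0.2
        assert f_rev < 0.02

    def test_equals_bruteforce_ols_ratio(self):
        """Oracle: two independent lstsq fits and the ln variance ratio."""
        rng = np.random.default_rng(10)
        x = rng.standard_normal((3, 400))
        p, tgt, src = 2, 0, 2
        n = x.shape[1]
        full_cols = [x[v, p - j:n - j] for v in range(3)
                     for j in range(1, p + 1)]
        X_full = np.column_stack(full_cols + [np.ones(n - p)])
        X_restr = np.column_stack(
            [x[v, p - j:n - j] for v in range(3) if v != src
             for j in range(1, p + 1)] + [np.ones(n - p)])
        y = x[tgt, p:]
        r_full = y - X_full @ np.linalg.lstsq(X_full, y, rcond=None)[0]
        r_restr = y - X_restr @ np.linalg.lstsq(X_restr, y, rcond=None)[0]
        expect = np.log((r_restr @ r_restr) / (r_full @ r_full))
        got = conditional_gc(x, target=tgt, source=src, p=p)
        assert got == pytest.approx(expect, abs=1e-10)

    def test_affine_rescaling_invariance(self, bivariate_coupled):
        x = bivariate_coupled
        y = np.vstack([3.0 * x[0] - 7.0, -0.5 * x[1] + 2.0])
        f1 = conditional_gc(x, 1, 0, p=1)
        f2 = conditional_gc(y, 1, 0, p=1)
        assert f1 == pytest.approx(f2, rel=1e-8)

    def test_nonnegative_for_nested_models(self):
        rng = np.random.default_rng(11)
        for seed in range(5):
            x = np.random.default_rng(seed).standard_normal((3, 800))
            assert conditional_gc(x, 0, 1, p=3) >= -1e-12

    def test_bivariate_reduces_to_pairwise(self, bivariate_coupled):
        """With only two series the conditioning set is empty, so the
        conditional statistic equals a plain pairwise implementation."""
        x = bivariate_coupled
        p = 1
        n = x.shape[1]
        # pairwise implementation from scratch
        X_full = np.column_stack([x[0, :-1], x[1, :-1], np.ones(n - 1)])
        X_restr = np.column_stack([x[1, :-1], np.ones(n - 1)])
        y = x[1, 1:]
        r_f = y - X_full @ np.linalg.lstsq(X_full, y, rcond=None)[0]
        r_r = y - X_restr @ np.linalg.lstsq(X_restr, y, rcond=None)[0]
        pairwise = np.log((r_r @ r_r) / (r_f @ r_f))
        assert conditional_gc(x, 1, 0, p) == pytest.approx(pairwise,
                                                           abs=1e-10)

    def test_source_equals_target_rejected(self):
        with pytest.raises(ValueError):
            conditional_gc(np.zeros((3, 100)), 1, 1, p=1)


class TestSignificance:
    def test_pvalues_in_unit_interval(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((3, 600))
        res = significance(x, p=2, n_perm=99, seed=0)
        off = ~np.eye(3, dtype=bool)
        assert np.all(res.pvals[off] > 0.0)
        assert np.all(res.pvals[off] <= 1.0)

    def test_planted_coupling_significant(self, bivariate_coupled):
        res = significance(bivariate_coupled, p=1, n_perm=199, alpha=0.01,
                           seed=3)
        assert res.adjacency[1, 0]          # x -> y detected
        assert not res.adjacency[0, 1]      # no reverse edge

    def test_nperm_minimum_enforced(self):
        with pytest.raises(ValueError):
            significance(np.zeros((2, 100)), p=1, n_perm=50)

    def test_matches_bruteforce_f_values(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal((3, 500))
        res = significance(x, p=2, n_perm=99, seed=1)
        for s in range(3):
            for t in range(3):
                if s == t:
                    continue
                assert res.F[t, s] == pytest.approx(
                    conditional_gc(x, t, s, p=2), abs=1e-10)


class TestPrewhiten:
    def test_removes_own_predictability(self):
        coefs = np.zeros((1, 1, 1))
        coefs[0, 0, 0] = 0.9
        x = simulate_var(coefs, 4000, seed=14)
        w = prewhiten(x, order=5)
        # lag-1 autocorrelation of the residuals is near zero
        r = np.corrcoef(w[0, 1:], w[0, :-1])[0, 1]
        assert abs(r) < 0.05

    def test_preserves_directed_coupling(self, bivariate_coupled):
        w = prewhiten(bivariate_coupled, order=10)
        assert conditional_gc(w, 1, 0, p=1) > 0.1
        assert conditional_gc(w, 0, 1, p=1) < 0.02

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            prewhiten(np.zeros((2, 30)), order=20)


class TestConnectivityResultExports:
    def _result(self, coupled=True):
        x = (simulate_var(np.array([[[0.4, 0.0], [0.7, 0.2]]]).reshape(2, 2, 1),
                          3000, seed=15)
             if coupled else
             np.random.default_rng(16).standard_normal((2, 3000)))
        return ConditionalGC(x, labels=["A", "B"], p=1,
                             prewhiten_order=None).fit(n_perm=199, seed=2)

    def test_no_significant_edges_empty_list(self):
        res = self._result(coupled=False)
        assert len(res.edges()) == 0
        assert len(connectivity_graph(["A", "B"], res)) == 0

    def test_single_true_edge_exported(self):
        res = self._result(coupled=True)
        edges = res.edges()
        assert len(edges) == 1
        assert edges.iloc[0]["source"] == "A"
        assert edges.iloc[0]["target"] == "B"
        g = res.to_graph()
        assert list(g.edges) == [("A", "B")]

    def test_summary_mentions_edges(self):
        res = self._result(coupled=True)
        assert "A -> B" in res.summary()
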