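import numpy as np
import pandas as pd
import pytest

from panarch import (
    PGLS,
    PagelsLambda,
    broken_stick_select,
    cophenetic_matrix,
    lambda_transform,
    pagels_lambda,
    pc_decompose,
    phylo_covariance,
    simulate_tree,
    tree_from_string,
)
from panarch.errors import TreeError

# fixed 8-tip fixture; the frozen lambda/logL reference values below were
# computed independently with R phytools::phylosig on this exact tree+trait
FIXTURE_NEWICK = (
    "(((A:0.3,B:0.3):0.4,(C:0.5,D:0.5):0.2):0.3,"
    "((E:0.2,F:0.2):0.5,(G:0.4,H:0.4):0.3):0.3);"
)
FIXTURE_TRAIT = dict(A=1.2, B=1.0, C=-0.4, D=-0.1, E=0.6, F=0.9, G=-1.1, H=-0.8)
FIXTURE_LAMBDA = 1.193418
FIXTURE_LOGL = -7.645245


class TestTreeMatrices:
    def test_two_leaf_path_sum(self):
        t = tree_from_string("(A:1,B:2);")
        D = cophenetic_matrix(t)
        assert D.loc["A", "B"] == pytest.approx(3.0)

    def test_three_leaf_manual(self):
        t = tree_from_string("((A:1,B:1):1,C:2);")
        D = cophenetic_matrix(t)
        assert D.loc["A", "B"] == pytest.approx(2.0)
        assert D.loc["A", "C"] == pytest.approx(4.0)
        assert D.loc["B", "C"] == pytest.approx(4.0)

    def test_triangle_inequality_random_trees(self):
        for seed in range(20):
            t = simulate_tree(8, seed=seed)
            D = cophenetic_matrix(t).to_numpy()
            n = D.shape[0]
            for i in range(n):
                for j in range(n):
                    for k in range(n):
                        assert D[i, j] <= D[i, k] + D[k, j] + 1e-9

    def test_ultrametric_root_to_tip(self):
        # pure-birth trees are ultrametric: covariance diagonal all equal
        t = simulate_tree(12, seed=3)
        C = phylo_covariance(t)
        assert np.allclose(np.diag(C.to_numpy()), C.to_numpy()[0, 0])

    def test_covariance_consistent_with_cophenetic(self):
        # d(i,j) = C[i,i] + C[j,j] - 2 C[i,j]
        t = simulate_tree(10, seed=9)
        C = phylo_covariance(t).to_numpy()
        D = cophenetic_matrix(t).to_numpy()
        expected = np.diag(C)[:, None] + np.diag(C)[None, :] - 2 * C
        assert np.allclose(D, expected, atol=1e-9)

    def test_missing_branch_length(self):
        t = tree_from_string("(A:1,(B,C:1):1);")
        with pytest.raises(TreeError):
            phylo_covariance(t)


class TestPCA:
    def test_rank_one_single_component(self):
        v = np.arange(5, dtype=float)
        X = pd.DataFrame(np.outer(v, [1.0, 2.0, -1.0]))
        dec = pc_decompose(X, scale_columns=False)
        assert dec.explained_fraction[0] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((12, 5)))
        dec = pc_decompose(X)
        assert dec.explained_fraction.sum() == pytest.approx(1.0)

    def test_matches_correlation_eigendecomposition(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((5, 3)))
        dec = pc_decompose(X, scale_columns=True)
        R = np.corrcoef(X.to_numpy(), rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(R))[::-1]
        assert np.allclose(dec.explained_fraction[: len(eig)], eig / eig.sum(), atol=1e-10)

    def test_distance_preservation_unscaled(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((10, 4)))
        dec = pc_decompose(X, scale_columns=False)
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(X - X.mean()), pdist(dec.scores), atol=1e-8)

    def test_constant_column_dropped(self, caplog):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
        with caplog.at_level("WARNING"):
            dec = pc_decompose(X)
        assert dec.scores.shape[1] == 1


class TestBrokenStick:
    def test_two_component_case(self):
        # b = (0.75, 0.25): 0.9 > 0.75 retains the first, 0.1 < 0.25 stops
        assert broken_stick_select([0.9, 0.1]) == 1

    def test_uniform_fractions_retain_none(self):
        for p in (2, 4, 8):
            assert broken_stick_select([1 / p] * p) == 0

    def test_three_component_case(self):
        # b = (11/18, 5/18, 2/18); 0.7 > 11/18 but 0.25 < 5/18
        assert broken_stick_select([0.7, 0.25, 0.05]) == 1


class TestLambdaTransform:
    def test_identity_and_star(self):
        C = np.array([[2.0, 1.0, 0.5], [1.0, 2.0, 0.3], [0.5, 0.3, 1.5]])
        assert np.array_equal(lambda_transform(C, 1.0), C)
        assert np.array_equal(lambda_transform(C, 0.0), np.diag(np.diag(C)))

    def test_half(self):
        C = np.array([[2.0, 1.0], [1.0, 2.0]])
        V = lambda_transform(C, 0.5)
        assert V[0, 1] == 0.5 and V[0, 0] == 2.0


class TestPagelsLambda:
    def test_frozen_reference_fixture(self):
        """Estimate matches an independent reference implementation."""
        t = tree_from_string(FIXTURE_NEWICK)
        res = pagels_lambda(t, pd.Series(FIXTURE_TRAIT))
        assert res.lambda_ == pytest.approx(FIXTURE_LAMBDA, abs=1e-4)
        assert res.loglik == pytest.approx(FIXTURE_LOGL, abs=1e-5)

    def test_brownian_recovery_small(self):
        tree = simulate_tree(60, seed=5)
        C = phylo_covariance(tree)
        L = np.linalg.cholesky(C.to_numpy())
        rng = np.random.default_rng(6)
        lams = []
        for _ in range(20):
            y = pd.Series(L @ rng.standard_normal(60), index=C.index)
            lams.append(PagelsLambda(C, y).fit().lambda_)
        assert 0.85 <= np.mean(lams) <= 1.05

    def test_permuted_trait_loses_signal(self):
        tree = simulate_tree(60, seed=5)
        C = phylo_covariance(tree)
        L = np.linalg.cholesky(C.to_numpy())
        rng = np.random.default_rng(8)
        lams = []
        for _ in range(10):
            y = L @ rng.standard_normal(60)
            lams.append(PagelsLambda(C, pd.Series(rng.permutation(y), index=C.index)).fit().lambda_)
        assert np.median(lams) < 0.1

    def test_star_tree_degenerate(self):
        n = 10
        C = pd.DataFrame(np.eye(n), index=[f"t{i}" for i in range(n)],
                         columns=[f"t{i}" for i in range(n)])
        rng = np.random.default_rng(3)
        y = pd.Series(rng.standard_normal(n), index=C.index)
        res = PagelsLambda(C, y).fit()
        assert res.degenerate
        assert res.ci95 == (0.0, res.lambda_max)

    def test_loglik_at_mode_beats_endpoints(self):
        tree = simulate_tree(40, seed=10)
        trait, _ = __import__("panarch").simulate_trait(tree, lam=0.5, sigma2=1.0, seed=2)
        model = PagelsLambda(phylo_covariance(tree), trait)
        res = model.fit()
        assert res.loglik >= model.loglik(0.0) - 1e-9
        assert res.loglik >= model.loglik(res.lambda_max) - 1e-9
        assert res.ci95[0] <= res.lambda_ <= res.ci95[1]


class TestPGLS:
    def _setup(self, n=50, seed=0):
        tree = simulate_tree(n, seed=seed)
        C = phylo_covariance(tree)
        rng = np.random.default_rng(seed + 1)
        X = pd.DataFrame({"x": rng.standard_normal(n)}, index=C.index)
        return tree, C, X, rng

    def test_lambda_zero_equals_ols(self):
        tree, C, X, rng = self._setup()
        y = pd.Series(2 + 0.5 * X["x"] + 0.1 * rng.standard_normal(len(X)), index=X.index)
        fit = PGLS(C, y, X).fit(lambda_=0.0)
        import statsmodels.api as sm

        ols = sm.OLS(y.to_numpy(), sm.add_constant(X.to_numpy())).fit()
        assert fit.params["Intercept"] == pytest.approx(ols.params[0], abs=1e-8)
        assert fit.params["x"] == pytest.approx(ols.params[1], abs=1e-8)

    def test_star_tree_equals_ols(self):
        n = 30
        ids = [f"t{i}" for i in range(n)]
        C = pd.DataFrame(np.eye(n), index=ids, columns=ids)
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"x": rng.standard_normal(n)}, index=ids)
        y = pd.Series(1 + 2 * X["x"] + rng.standard_normal(n), index=ids)
        fit = PGLS(C, y, X).fit()
        import statsmodels.api as sm

        ols = sm.OLS(y.to_numpy(), sm.add_constant(X.to_numpy())).fit()
        assert fit.params["x"] == pytest.approx(ols.params[1], abs=1e-6)

    def test_slope_recovery_brownian_noise(self):
        slopes = []
        for seed in range(15):
            tree, C, X, rng = self._setup(n=50, seed=100 + seed)
            L = np.linalg.cholesky(C.to_numpy())
            noise = 0.5 * (L @ rng.standard_normal(50))
            y = pd.Series(2 + 0.5 * X["x"].to_numpy() + noise, index=C.index)
            slopes.append(PGLS(C, y, X).fit().params["x"])
        assert abs(np.mean(slopes) - 0.5) < 0.05

    def test_partial_r2_range_and_reporting(self):
        tree, C, X, rng = self._setup(seed=7)
        X["z"] = rng.standard_normal(len(X))
        y = pd.Series(0.8 * X["x"] + 0.1 * rng.standard_normal(len(X)), index=X.index)
        fit = PGLS(C, y, X).fit()
        assert set(fit.partial_r2.index) == {"x", "z"}
        assert ((fit.partial_r2 >= 0) & (fit.partial_r2 <= 1)).all()
        assert fit.partial_r2["x"] > fit.partial_r2["z"]
        assert "partial R2" in fit.summary()

    def test_collinear_design_rejected(self):
        tree, C, X, rng = self._setup()
        X["x2"] = 2 * X["x"]
        y = pd.Series(rng.standard_normal(len(X)), index=X.index)
        with pytest.raises(ValueError, match="rank"):
            PGLS(C, y, X)
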