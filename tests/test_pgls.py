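"""Phylogenetic covariance, Pagel transforms, GLS estimation, and ML optimization."""

import numpy as np
import pytest
import statsmodels.api as sm

from fishcnv import pgls
from fishcnv.pgls import BranchTransforms, PhyloCovariance
from fishcnv.phylo_io import read_newick

from conftest import random_trees


def brute_force_vcv(tree):
    """Shared-path enumeration oracle: V_ij = summed length of edges common
    to the root->i and root->j paths."""
    paths = {}

    def walk(node, edges):
        edges = edges + [(id(node), node.length)]
        if node.is_leaf:
            paths[node.label] = edges
        for ch in node.children:
            walk(ch, edges)

    for ch in tree.root.children:
        walk(ch, [])
    taxa = sorted(paths)
    n = len(taxa)
    V = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            ids_b = {e for e, _ in paths[b]}
            V[i, j] = sum(l for e, l in paths[a] if e in ids_b)
    return taxa, V


class TestVCV:
    def test_two_leaf(self):
        cov = pgls.vcv_from_tree(read_newick("(A:1,B:1);"))
        assert np.array_equal(cov.V, np.eye(2))

    def test_three_leaf_hand_computed(self):
        cov = pgls.vcv_from_tree(read_newick("((A:1,B:1):1,C:2);"))
        idx = {t: i for i, t in enumerate(cov.taxa)}
        a, b, c = idx["a"], idx["b"], idx["c"]
        assert cov.V[a, a] == cov.V[b, b] == cov.V[c, c] == 2
        assert cov.V[a, b] == 1
        assert cov.V[a, c] == cov.V[b, c] == 0

    def test_matches_brute_force_enumeration(self):
        for tree in random_trees(40, n_taxa_range=(3, 8), seed=13):
            taxa, V_expected = brute_force_vcv(tree)
            cov = pgls.vcv_from_tree(tree).reorder(taxa)
            assert np.allclose(cov.V, V_expected, rtol=1e-12, atol=0.0)

    def test_zero_depth_tree_error(self):
        with pytest.raises(ValueError, match="zero depth"):
            pgls.vcv_from_tree(read_newick("(A:0,B:0);"))


class TestTransforms:
    def test_kappa_identity(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        assert pgls.apply_kappa(t, 1.0).to_newick() == t.to_newick()

    def test_kappa_powers_branches(self):
        t = pgls.apply_kappa(read_newick("(A:3,B:2);"), 2.0)
        assert t.leaf_depths() == {"a": 9.0, "b": 4.0}

    def test_kappa_zero_equalizes_positive_branches(self):
        t = pgls.apply_kappa(read_newick("((A:1,B:0.5):2,C:2);"), 0.0)
        assert all(d == pytest.approx(1.0) or d == pytest.approx(2.0) for d in t.leaf_depths().values())
        assert t.leaf_depths() == {"a": 2.0, "b": 2.0, "c": 1.0}

    def test_negative_kappa_error(self):
        with pytest.raises(ValueError):
            pgls.apply_kappa(read_newick("(A:1,B:1);"), -1.0)

    def test_delta_identity(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        assert pgls.apply_delta(t, 1.0).to_newick() == t.to_newick()

    def test_delta_hand_computed(self):
        # node depths {1, 2}; delta=2 -> {1, 4}; C's terminal branch 2 -> 4
        t = pgls.apply_delta(read_newick("((A:1,B:1):1,C:2);"), 2.0)
        assert t.leaf_depths() == {"a": 4.0, "b": 4.0, "c": 4.0}
        cov = pgls.vcv_from_tree(t)
        idx = {x: i for i, x in enumerate(cov.taxa)}
        assert cov.V[idx["a"], idx["b"]] == pytest.approx(1.0)  # mrca depth 1 -> 1**2

    def test_delta_vcv_is_elementwise_power(self):
        for tree in random_trees(15, seed=17):
            delta = 1.7
            V0 = pgls.vcv_from_tree(tree).V
            V1 = pgls.vcv_from_tree(pgls.apply_delta(tree, delta)).V
            assert np.allclose(V1, V0**delta, rtol=1e-9)

    def test_delta_requires_ultrametric(self):
        with pytest.raises(ValueError, match="ultrametric"):
            pgls.apply_delta(read_newick("((A:1,B:1):1,C:5);"), 2.0)

    def test_lambda_scales_off_diagonal(self):
        cov = pgls.vcv_from_tree(read_newick("((A:1,B:1):1,C:2);"))
        half = pgls.apply_lambda(cov, 0.5)
        idx = {t: i for i, t in enumerate(cov.taxa)}
        assert half.V[idx["a"], idx["b"]] == pytest.approx(0.5)
        assert np.array_equal(np.diag(half.V), np.diag(cov.V))
        zero = pgls.apply_lambda(cov, 0.0)
        assert np.array_equal(zero.V, np.diag(np.diag(cov.V)))

    def test_lambda_bounds(self):
        cov = pgls.vcv_from_tree(read_newick("(A:1,B:1);"))
        for bad in (-0.1, 1.1):
            with pytest.raises(ValueError):
                pgls.apply_lambda(cov, bad)

    def test_identity_transforms_leave_builder_vcv_unchanged(self):
        for tree in random_trees(10, seed=19):
            b = pgls.CovarianceBuilder(tree)
            assert np.allclose(b.vcv(BranchTransforms()), pgls.vcv_from_tree(tree).reorder(b.taxa).V)

    def test_transformed_vcv_stays_psd(self):
        rng = np.random.default_rng(23)
        for tree in random_trees(10, seed=29):
            b = pgls.CovarianceBuilder(tree)
            tr = BranchTransforms(
                kappa=float(rng.uniform(0.01, 3)), lam=float(rng.uniform(0, 1)), delta=float(rng.uniform(0.1, 3))
            )
            V = b.vcv(tr)
            eig = np.linalg.eigvalsh(V)
            assert eig.min() >= -1e-8 * np.trace(V)


def random_instance(rng, n=30, k=3):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
    beta = rng.normal(size=k)
    y = X @ beta + rng.normal(size=n)
    return X, y


class TestGLS:
    def test_exact_fit(self):
        x = np.arange(10.0)
        X = np.column_stack([np.ones(10), x])
        fit = pgls.gls_fit(X, x, np.eye(10), terms=["intercept", "x"])
        assert fit.coef("x") == pytest.approx(1.0, abs=1e-12)
        assert fit.coef("intercept") == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_identity_v_matches_ols(self, rng):
        """With V = I, every field degenerates to textbook OLS (statsmodels)."""
        for _ in range(10):
            X, y = random_instance(rng)
            fit = pgls.gls_fit(X, y, np.eye(len(y)))
            ols = sm.OLS(y, X).fit()
            assert np.allclose(fit.coefficients, ols.params, atol=1e-10)
            assert np.allclose(fit.standard_errors, ols.bse, atol=1e-10)
            assert np.allclose(fit.t_values, ols.tvalues, atol=1e-8)
            assert np.allclose(fit.p_values, ols.pvalues, atol=1e-10)
            assert fit.r_squared == pytest.approx(ols.rsquared, abs=1e-10)
            assert fit.log_likelihood == pytest.approx(ols.llf, abs=1e-8)

    def test_general_v_matches_statsmodels_gls(self, rng):
        for _ in range(5):
            X, y = random_instance(rng)
            A = rng.normal(size=(len(y), len(y)))
            V = A @ A.T + len(y) * np.eye(len(y))
            fit = pgls.gls_fit(X, y, V)
            gls = sm.GLS(y, X, sigma=V).fit()
            assert np.allclose(fit.coefficients, gls.params, atol=1e-10)
            assert np.allclose(fit.standard_errors, gls.bse, atol=1e-10)
            assert np.allclose(fit.p_values, gls.pvalues, atol=1e-10)

    def test_scale_equivariance(self, rng):
        X, y = random_instance(rng)
        V = np.eye(len(y))
        f1 = pgls.gls_fit(X, y, V)
        f2 = pgls.gls_fit(X, 3.7 * y, V)
        assert np.allclose(f2.coefficients, 3.7 * f1.coefficients)
        assert np.allclose(f2.standard_errors, 3.7 * f1.standard_errors)
        assert np.allclose(f2.t_values, f1.t_values)
        assert np.allclose(f2.p_values, f1.p_values)
        assert f2.r_squared == pytest.approx(f1.r_squared)

    def test_collinearity_reported(self, rng):
        n = 20
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(ValueError, match="collinear.*dup"):
            pgls.gls_fit(X, rng.normal(size=n), np.eye(n), terms=["intercept", "x", "dup"])

    def test_needs_more_rows_than_columns(self, rng):
        X = np.ones((3, 3))
        with pytest.raises(ValueError, match="n > k"):
            pgls.gls_fit(X, np.zeros(3), np.eye(3))


class TestProfileLoglik:
    def test_identity_transforms_match_gls_fit(self):
        tree = random_trees(1, n_taxa_range=(8, 8), seed=31)[0]
        rng = np.random.default_rng(1)
        n = tree.n_leaves()
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        fit = pgls.gls_fit(X, y, pgls.vcv_from_tree(tree))
        ll = pgls.profile_loglik(tree, X, y, BranchTransforms())
        assert ll == pytest.approx(fit.log_likelihood, abs=1e-9)

    def test_permutation_invariance(self):
        tree = random_trees(1, n_taxa_range=(7, 7), seed=37)[0]
        rng = np.random.default_rng(2)
        b = pgls.CovarianceBuilder(tree)
        n = len(b.taxa)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        ll = pgls.profile_loglik(tree, X, y, BranchTransforms(lam=0.6))
        perm = rng.permutation(n)
        V = b.vcv(BranchTransforms(lam=0.6))[np.ix_(perm, perm)]
        fit = pgls.gls_fit(X[perm], y[perm], V)
        assert fit.log_likelihood == pytest.approx(ll, abs=1e-9)


class TestOptimize:
    def test_optimized_dominates_fixed(self):
        rng = np.random.default_rng(3)
        for tree in random_trees(5, n_taxa_range=(10, 14), seed=41):
            n = tree.n_leaves()
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            y = rng.normal(size=n)
            ll_fixed = pgls.profile_loglik(tree, X, y, BranchTransforms())
            _, fit = pgls.optimize_transforms(tree, X, y)
            assert fit.log_likelihood >= ll_fixed - 1e-8

    def test_star_data_recovers_low_lambda(self):
        from fishcnv import synthetic_data as sd

        lams = []
        for s in range(12):
            cfg = sd.SimConfig(seed=5000 + s, n_taxa=50, true_lambda=0.0)
            tree = sd.simulate_yule_tree(cfg)
            b = pgls.CovarianceBuilder(tree)
            rng = np.random.default_rng(600 + s)
            x = rng.normal(size=50)
            e = np.linalg.cholesky(b.vcv(BranchTransforms(lam=0.0)) + 1e-12 * np.eye(50)) @ rng.standard_normal(50)
            y = 1.0 + 0.5 * x + 0.6 * e
            tr, _ = pgls.optimize_transforms(b, np.column_stack([np.ones(50), x]), y)
            lams.append(tr.lam)
        assert np.mean(lams) <= 0.1

    def test_bound_hit_flagged(self):
        rng = np.random.default_rng(4)
        tree = random_trees(1, n_taxa_range=(12, 12), seed=43)[0]
        n = tree.n_leaves()
        X = np.ones((n, 1))
        y = rng.normal(size=n)  # independent noise: lambda should slam to 0
        tr, _ = pgls.optimize_transforms(tree, X, y, terms=["intercept"])
        if tr.lam <= 1e-6:
            assert "lambda" in tr.at_bound


class TestBonferroni:
    def test_paper_family_size(self):
        assert f"{pgls.bonferroni_threshold(0.05, 39):.3g}" == "0.00128"

    def test_single_test(self):
        assert pgls.bonferroni_threshold(0.05, 1) == 0.05

    def test_five_hundred_tests(self):
        # p <= 0.0001 stays significant for families up to 500 tests
        assert pgls.bonferroni_threshold(0.05, 500) == pytest.approx(0.0001)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            pgls.bonferroni_threshold(0.05, 0)
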