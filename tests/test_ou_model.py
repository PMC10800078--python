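import numpy as np
import pytest
from scipy import stats

from oushift import (
    OUParams,
    PhyloTree,
    ShiftConfiguration,
    estimate_alpha_sigma,
    gen_tree,
    gls_fit,
    log_likelihood,
    mean_vector,
    ou_covariance,
    read_newick,
    simulate_traits,
    whiten,
)
from oushift.ou_model import _structure_matrix


class TestCovariance:
    def test_stationary_variance_is_one(self, coalescent20):
        Sigma = ou_covariance(coalescent20, OUParams(1.0, 2.0))
        np.testing.assert_allclose(np.diag(Sigma), 1.0)

    def test_bm_limit_is_shared_time(self, coalescent20):
        Sigma = ou_covariance(coalescent20, OUParams(0.0, 1.0))
        t = coalescent20.shared_time_matrix()
        np.testing.assert_allclose(Sigma, t, atol=1e-6 * np.trace(t))

    def test_off_diagonal_closed_form(self, cherry):
        Sigma = ou_covariance(cherry, OUParams(1.0, 2.0))
        assert Sigma[0, 1] == pytest.approx(np.exp(-2.0))  # d_AB = 2

    def test_small_alpha_correlation_approaches_one(self, cherry):
        params = OUParams(1e-6, 2e-6)
        Sigma = ou_covariance(cherry, params)
        corr = Sigma[0, 1] / Sigma[0, 0]
        assert corr == pytest.approx(1.0, abs=1e-5)


class TestMeanVector:
    def test_no_shifts_constant(self, three_tip):
        mu = mean_vector(three_tip, OUParams(1.0, 2.0, beta0=3.5))
        np.testing.assert_allclose(mu, 3.5)

    def test_single_shift_offsets_descendants(self, three_tip):
        stem = next(b.id for b in three_tip.branches if len(b.descendant_tips) == 2)
        shifts = ShiftConfiguration(((stem, 2.0),))
        mu = mean_vector(three_tip, OUParams(1.0, 2.0), shifts)
        lab = three_tip.tip_labels
        assert mu[lab.index("A")] == mu[lab.index("B")] == pytest.approx(2.0)
        assert mu[lab.index("C")] == pytest.approx(0.0)

    def test_matches_per_tip_path_sum(self, coalescent20, rng):
        beta = rng.normal(size=coalescent20.n_branches)
        shifts = ShiftConfiguration(tuple(enumerate(beta)))
        mu = mean_vector(coalescent20, OUParams(1.0, 2.0, beta0=1.0), shifts)
        for i in range(coalescent20.n_tips):
            expected = 1.0 + sum(beta[b] for b in coalescent20.tip_path(i))
            assert mu[i] == pytest.approx(expected)

    def test_optimum_change_conversion(self, three_tip):
        stem = next(b.id for b in three_tip.branches if len(b.descendant_tips) == 2)
        alpha = 0.7
        dtheta = 3.0
        shifts = ShiftConfiguration(((stem, dtheta),), as_optimum_change=True)
        mu = mean_vector(three_tip, OUParams(alpha, 2.0), shifts)
        t_start = three_tip.branches[stem].t_start
        expected = (1 - np.exp(-alpha * t_start)) * dtheta
        assert mu[three_tip.tip_labels.index("A")] == pytest.approx(expected)


class TestWhitening:
    def test_identity_input(self):
        np.testing.assert_allclose(whiten(np.eye(4)), np.eye(4))

    def test_defining_property_random_pd(self, rng):
        A = rng.normal(size=(10, 10))
        Sigma = A @ A.T + 10 * np.eye(10)
        W = whiten(Sigma)
        np.testing.assert_allclose(W @ Sigma @ W.T, np.eye(10), atol=1e-10)

    def test_agrees_with_eigendecomposition_whitener(self, rng):
        A = rng.normal(size=(10, 10))
        Sigma = A @ A.T + 10 * np.eye(10)
        vals, vecs = np.linalg.eigh(Sigma)
        W_eig = vecs @ np.diag(vals ** -0.5) @ vecs.T
        for W in (whiten(Sigma), W_eig):  # both whiten, up to rotation
            np.testing.assert_allclose(W @ Sigma @ W.T, np.eye(10), atol=1e-9)

    def test_non_pd_rejected_with_eigenvalue(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="eigenvalue"):
            whiten(bad)


class TestGLS:
    def test_intercept_closed_form(self, coalescent20, rng):
        Y = rng.normal(size=20)
        fit = gls_fit(coalescent20, Y, (), alpha=1.0)
        Sinv = np.linalg.inv(_structure_matrix(coalescent20, 1.0))
        one = np.ones(20)
        expected = (one @ Sinv @ Y) / (one @ Sinv @ one)
        assert fit.beta0 == pytest.approx(expected, rel=1e-8)

    def test_noiseless_exact_recovery(self, coalescent20):
        branches = (5, 20)
        shifts = ShiftConfiguration(((5, 3.0), (20, -1.5)))
        Y = mean_vector(coalescent20, OUParams(1.0, 2.0, beta0=0.7), shifts)
        fit = gls_fit(coalescent20, Y, branches, alpha=1.0)
        assert fit.beta0 == pytest.approx(0.7, abs=1e-8)
        np.testing.assert_allclose(sorted(fit.beta), [-1.5, 3.0], atol=1e-8)

    def test_matches_brute_force_normal_equations(self, coalescent20, rng):
        Y = rng.normal(size=20)
        branches = (3, 11, 30)
        fit = gls_fit(coalescent20, Y, branches, alpha=0.8)
        Sinv = np.linalg.inv(_structure_matrix(coalescent20, 0.8))
        X = coalescent20.incidence_matrix()
        A = np.column_stack([np.ones(20)] + [X[:, b] for b in branches])
        coef = np.linalg.solve(A.T @ Sinv @ A, A.T @ Sinv @ Y)
        assert fit.beta0 == pytest.approx(coef[0], rel=1e-8)
        np.testing.assert_allclose(fit.beta, coef[1:], rtol=1e-8)
        resid = Y - A @ coef
        assert fit.sigma2 == pytest.approx(resid @ Sinv @ resid / 20, rel=1e-8)

    def test_shift_equivariance_under_translation(self, coalescent20, rng):
        Y = rng.normal(size=20)
        f1 = gls_fit(coalescent20, Y, (4, 9), alpha=1.0)
        f2 = gls_fit(coalescent20, Y + 11.0, (4, 9), alpha=1.0)
        assert f2.beta0 == pytest.approx(f1.beta0 + 11.0)
        np.testing.assert_allclose(f2.beta, f1.beta, atol=1e-9)

    def test_rank_deficient_design_names_clash(self):
        # a unary chain gives two branches with identical descendant sets
        parent = np.array([-1, 0, 0, 2, 3, 3])
        lengths = np.array([0.0, 2.0, 0.5, 0.5, 1.0, 1.0])
        labels = {1: "A", 4: "B", 5: "C"}
        tree = PhyloTree(parent, lengths, labels)
        dup = [b.id for b in tree.branches if b.descendant_tips == frozenset({
            tree.tip_labels.index("B"), tree.tip_labels.index("C")})]
        assert len(dup) == 2
        with pytest.raises(ValueError, match="collinear"):
            gls_fit(tree, np.array([1.0, 2.0, 3.0]), dup, alpha=1.0)


class TestLikelihood:
    def test_matches_scipy_multivariate_normal(self, coalescent20, rng):
        params = OUParams(1.3, 2.2, beta0=0.4)
        shifts = ShiftConfiguration(((7, 2.0),))
        Y = rng.normal(size=20)
        ours = log_likelihood(coalescent20, Y, params, shifts)
        ref = stats.multivariate_normal.logpdf(
            Y, mean=mean_vector(coalescent20, params, shifts),
            cov=ou_covariance(coalescent20, params))
        assert ours == pytest.approx(ref, rel=1e-10)

    def test_cherry_density_closed_form(self):
        tree = read_newick("(A:1,B:1);")
        params = OUParams(1.0, 2.0)  # unit variance, correlation e^{-2}
        ll = log_likelihood(tree, np.zeros(2), params)
        expected = -np.log(2 * np.pi) - 0.5 * np.log(1 - np.exp(-4.0))
        assert ll == pytest.approx(expected)

    def test_nested_model_likelihood_monotone(self, coalescent20, rng):
        Y = rng.normal(size=20)
        prev = -np.inf
        for branches in [(), (5,), (5, 12), (5, 12, 30)]:
            ll = gls_fit(coalescent20, Y, branches, alpha=1.0).loglik
            assert ll >= prev - 1e-9
            prev = ll

    def test_true_shift_improves_noiseless_fit(self, coalescent20):
        shifts = ShiftConfiguration(((6, 4.0),))
        Y = mean_vector(coalescent20, OUParams(1.0, 2.0), shifts)
        Y = Y + 0.01 * np.sin(np.arange(20))  # break exact interpolation
        ll0 = gls_fit(coalescent20, Y, (), alpha=1.0).loglik
        ll1 = gls_fit(coalescent20, Y, (6,), alpha=1.0).loglik
        assert ll1 > ll0


class TestAlphaEstimation:
    def test_recovery_at_truth(self, birch100):
        true = (150, 120, 60)
        shifts = ShiftConfiguration.uniform(true, 10.0)
        alphas = [
            estimate_alpha_sigma(
                birch100, simulate_traits(birch100, OUParams(1.0, 2.0), shifts,
                                          rng=i), true).alpha
            for i in range(30)
        ]
        assert 0.5 <= np.median(alphas) <= 2.0

    def test_constant_trait_degenerate_input(self, coalescent20):
        fit = estimate_alpha_sigma(coalescent20, np.full(20, 3.0))
        assert np.isfinite(fit.alpha)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-12)

    def test_beats_random_probes(self, coalescent20, rng):
        Y = simulate_traits(coalescent20, OUParams(1.0, 2.0), rng=rng)
        best = estimate_alpha_sigma(coalescent20, Y)
        for _ in range(20):
            alpha = 10 ** rng.uniform(-4, 2)
            assert best.loglik >= gls_fit(coalescent20, Y, (), alpha).loglik - 1e-6


class TestSimulation:
    def test_stationary_tip_variance(self, coalescent20):
        rng = np.random.default_rng(7)
        draws = np.array([simulate_traits(coalescent20, OUParams(1.0, 2.0), rng=rng)
                          for _ in range(2000)])
        var = draws.var(axis=0).mean()
        # stationary variance 1; 3 SE of a pooled variance estimate
        assert var == pytest.approx(1.0, abs=0.1)

    def test_measurement_error_adds_variance(self, coalescent20):
        rng = np.random.default_rng(8)
        draws = np.array([
            simulate_traits(coalescent20, OUParams(1.0, 2.0), rng=rng,
                            measurement_sd=1.0)
            for _ in range(2000)])
        assert draws.var(axis=0).mean() == pytest.approx(2.0, abs=0.2)

    def test_recursive_simulator_matches_closed_form(self):
        tree = gen_tree("balanced", 8)
        rng = np.random.default_rng(9)
        params = OUParams(1.0, 2.0)
        # variance "shift" to the same value: must reproduce the closed form
        draws = np.array([
            simulate_traits(tree, params, rng=rng, variance_shift=(0, 2.0))
            for _ in range(3000)])
        np.testing.assert_allclose(np.cov(draws.T), ou_covariance(tree, params),
                                   atol=0.12)
        np.testing.assert_allclose(draws.mean(axis=0), 0.0, atol=0.1)

    def test_variance_shift_inflates_only_subtree(self):
        tree = gen_tree("balanced", 8)
        stem = next(b.id for b in tree.branches if len(b.descendant_tips) == 4)
        rng = np.random.default_rng(10)
        draws = np.array([
            simulate_traits(tree, OUParams(1.0, 2.0), rng=rng,
                            variance_shift=(stem, 8.0))
            for _ in range(2000)])
        inside = sorted(tree.branches[stem].descendant_tips)
        outside = [i for i in range(8) if i not in inside]
        assert draws[:, inside].var(axis=0).min() > 2.0
        assert draws[:, outside].var(axis=0).max() < 1.5

    def test_whitened_residuals_standard_normal(self, coalescent20):
        params = OUParams(1.0, 2.0)
        W = whiten(ou_covariance(coalescent20, params))
        rng = np.random.default_rng(11)
        pooled = np.concatenate([
            W @ simulate_traits(coalescent20, params, rng=rng)
            for _ in range(100)])
        assert stats.kstest(pooled, "norm").pvalue > 0.01

    def test_shift_magnitude_recovery(self, birch100):
        true = (150, 120, 60)
        shifts = ShiftConfiguration.uniform(true, 10.0)
        betas = np.array([
            gls_fit(birch100,
                    simulate_traits(birch100, OUParams(1.0, 2.0), shifts, rng=i),
                    true, alpha=1.0).beta
            for i in range(200)])
        np.testing.assert_allclose(betas.mean(axis=0), 10.0, rtol=0.05)
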