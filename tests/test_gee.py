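"""The phylogenetic estimating equations and their solver."""

import warnings

import numpy as np
import pytest
from oracle_gee import brute_force_roots

from phylocount import (
    NB2,
    CountGLM,
    CountRegData,
    PhyloGEE,
    Poisson,
    gee_score,
    parse_newick,
    tree_to_covariance,
)
from phylocount.families import DomainError
from phylocount.gee import fitted_values


class TestScore:
    def test_identity_C_reduces_to_glm_score(self, toy_aligned):
        """With C = I the quasi-score collapses to X'(Y - exp(X beta))."""
        data, _ = toy_aligned
        I = np.eye(data.n)
        for beta in ([0.0, 0.0], [1.0, 0.05], [-0.5, 0.1]):
            beta = np.array(beta)
            u = gee_score(beta, data, I, Poisson())
            expected = data.X.T @ (data.y - np.exp(data.X @ beta))
            np.testing.assert_allclose(u, expected, rtol=1e-9, atol=1e-9)

    def test_zero_at_independent_mle(self, toy_aligned):
        data, _ = toy_aligned
        beta_hat = CountGLM(data, "poisson").fit().params
        u = gee_score(beta_hat, data, np.eye(data.n), Poisson())
        np.testing.assert_allclose(u, 0.0, atol=1e-6)

    def test_rank_deficient_C_uses_pseudo_inverse(self):
        # duplicated tip rows make W singular: Cholesky must give way to pinv
        tree = parse_newick("((a:0.0,b:0.0):1.0,c:1.0);")
        C = tree_to_covariance(tree)
        assert np.linalg.matrix_rank(C.matrix) == 2
        y = np.array([3, 3, 7])
        data = CountRegData.from_arrays(y, np.array([0.1, 0.1, 0.9]),
                                        labels=C.labels)
        fit = PhyloGEE(data, C).fit()
        assert fit.used_pinv
        assert np.isfinite(fit.params).all()

    def test_canonical_domain_violation_names_tips(self, toy_aligned):
        data, C = toy_aligned
        fam = NB2(10.68, link="canonical")
        with pytest.raises(DomainError, match="eta < 0"):
            gee_score(np.array([1.0, 0.0]), data, C, fam)


class TestStarTreeEquivalence:
    def test_poisson_matches_glm(self, rng):
        for _ in range(5):
            x = rng.normal(size=20)
            y = rng.poisson(np.exp(1.2 + 0.4 * x))
            if (y > 0).sum() < 3:
                continue
            data = CountRegData.from_arrays(y, x)
            glm = CountGLM(data, "poisson").fit()
            for c in (1.0, 7.3):
                gee = PhyloGEE(data, c * np.eye(20)).fit()
                np.testing.assert_allclose(gee.params, glm.params, atol=1e-6)

    def test_nb2_fixed_r_matches_glm(self, rng):
        r = 4.0
        x = rng.normal(size=25)
        mu = np.exp(1.5 + 0.5 * x)
        y = rng.negative_binomial(r, r / (r + mu))
        data = CountRegData.from_arrays(y, x)
        glm = CountGLM(data, "nb2").fit(r=r)
        gee = PhyloGEE(data, np.eye(25), family=NB2(r, link="log")).fit()
        np.testing.assert_allclose(gee.params, glm.params, atol=1e-5)


class TestFitProperties:
    def test_permutation_invariance(self, toy_aligned):
        data, C = toy_aligned
        base = PhyloGEE(data, C).fit().params
        perm = [3, 0, 4, 1, 2]
        labels = [data.labels[i] for i in perm]
        data_p = CountRegData(labels, data.y[perm], data.X[perm], data.colnames)
        fit_p = PhyloGEE(data_p, C.reorder(labels)).fit()
        np.testing.assert_allclose(fit_p.params, base, atol=1e-8)

    def test_uniform_tree_rescaling_cancels(self, toy_aligned):
        data, C = toy_aligned
        b1 = PhyloGEE(data, C.matrix).fit().params
        b2 = PhyloGEE(data, C.matrix / 560.0).fit().params
        np.testing.assert_allclose(b1, b2, atol=1e-8)

    def test_exhausted_iterations_flagged_not_hidden(self, toy_aligned):
        data, C = toy_aligned
        with pytest.warns(RuntimeWarning, match="did not converge"):
            fit = PhyloGEE(data, C).fit(
                start_params=np.array([8.0, -1.0]), maxiter=1
            )
        assert not fit.converged
        assert np.isfinite(fit.score_norm)

    def test_non_psd_C_rejected(self, toy_aligned):
        data, _ = toy_aligned
        M = -np.eye(data.n)
        with pytest.raises(ValueError, match="positive semi-definite"):
            PhyloGEE(data, M)


class TestFittedValues:
    def test_zero_beta_poisson_gives_ones(self, toy_aligned):
        data, C = toy_aligned
        fit = PhyloGEE(data, C).fit()
        fit.params = np.zeros(2)
        np.testing.assert_allclose(fitted_values(fit, data.X), 1.0)

    def test_nb2_canonical_mean_formula(self):
        # mu = r e^eta / (1 - e^eta) at r = 10.68, eta = -1
        fam = NB2(10.68, link="canonical")
        expected = 10.68 * np.exp(-1) / (1 - np.exp(-1))
        assert fam.mean(np.array([-1.0]))[0] == pytest.approx(expected)
        assert expected == pytest.approx(6.2155, abs=5e-4)

    def test_roundtrip_identity_on_toy_fit(self, toy_aligned):
        data, C = toy_aligned
        fit = PhyloGEE(data, C).fit()
        np.testing.assert_allclose(
            fit.predict(data.X), np.exp(data.X @ fit.params), rtol=1e-12
        )

    def test_nb2_variance_relation(self):
        fam = NB2(10.68, link="canonical")
        eta = np.array([-2.0, -0.5])
        mu = fam.mean(eta)
        np.testing.assert_allclose(fam.dmu_deta(eta), mu + mu**2 / 10.68,
                                   rtol=1e-12)


class TestOracleAgreement:
    def test_solver_matches_brute_force_on_tiny_problems(self, rng):
        """n <= 3, p = 1: Newton root equals grid+bisection root to 1e-4."""
        checked = 0
        while checked < 5:
            n = int(rng.integers(2, 4))
            lens = rng.uniform(0.3, 2.0, size=2 * n)
            if n == 2:
                newick = f"(a:{lens[0]:.4f},b:{lens[1]:.4f});"
            else:
                newick = (
                    f"((a:{lens[0]:.4f},b:{lens[1]:.4f}):{lens[2]:.4f},"
                    f"c:{lens[3]:.4f});"
                )
            C = tree_to_covariance(parse_newick(newick))
            x = rng.normal(size=n)
            # a near-collinear design puts the (exact-fit) root at extreme
            # coefficients, outside the oracle's finite search box
            if np.ptp(x) < 0.8:
                continue
            y = rng.poisson(np.exp(1.0 + 0.5 * x))
            if np.any(y == 0):
                continue
            data = CountRegData.from_arrays(y, x, labels=C.labels)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                solver = PhyloGEE(data, C).fit()
            roots = brute_force_roots(data, C, Poisson())
            assert roots, "oracle found no root in the search box"
            # the system can have several roots; the solver's must be one
            gap = min(np.max(np.abs(solver.params - r)) for r in roots)
            assert gap <= 1e-4, (solver.params, roots)
            checked += 1
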