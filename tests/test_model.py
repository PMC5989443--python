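"""Objective, multiplicative updates and fit behaviour of the factorization."""

import dataclasses

import numpy as np
import pytest

import drivernmf as d
from drivernmf.model import FactorizationConfig, make_variant_config

from conftest import random_instance


def brute_force_objective(X, U, V, priors, cfg):
    """Term-by-term evaluation with explicit loops; no matrix identities."""
    n, p = X.shape
    K = U.shape[1]
    recon = 0.0
    for i in range(n):
        for j in range(p):
            recon += (X[i, j] - sum(U[i, k] * V[j, k] for k in range(K))) ** 2
    lw = priors.sample.L_W
    graph_u = sum(
        sum(U[i, k] * U[j, k] for k in range(K)) * lw[i, j]
        for i in range(n)
        for j in range(n)
    )
    ridge_u = sum(U[i, k] ** 2 for i in range(n) for k in range(K))
    lhat = priors.gene.L_hat
    graph_v = sum(
        sum(V[i, k] * V[j, k] for k in range(K)) * lhat[i, j]
        for i in range(p)
        for j in range(p)
    )
    sparse_v = sum(sum(abs(V[j, k]) for j in range(p)) ** 2 for k in range(K))
    return (
        recon
        + cfg.lambda_lu * graph_u
        + cfg.lambda_ru * ridge_u
        + cfg.lambda_lv * graph_v
        + cfg.lambda_rv * sparse_v
    )


def lee_seung_step(X, U, V, eps):
    """Independently coded classical multiplicative NMF sweep (U then V)."""
    U = U * ((X @ V) / (U @ V.T @ V + eps))
    V = V * ((X.T @ U) / (V @ U.T @ U + eps))
    return U, V


class TestObjective:
    def test_zero_factors_count_ones(self, rng):
        X, priors = random_instance(rng, 6, 7, 2)
        cfg = FactorizationConfig(K=2)
        U, V = np.zeros((6, 2)), np.zeros((7, 2))
        assert d.objective(X, U, V, priors, cfg) == pytest.approx(X.sum())

    def test_exact_factorization_no_penalty_is_zero(self, rng):
        _, priors = random_instance(rng, 5, 6, 2)
        U = rng.random((5, 2))
        V = rng.random((6, 2))
        X = U @ V.T
        cfg = FactorizationConfig(K=2, lambda_lu=0, lambda_ru=0, lambda_lv=0, lambda_rv=0)
        assert d.objective(X, U, V, priors, cfg) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n, p, K = rng.integers(3, 9), rng.integers(3, 11), rng.integers(1, 4)
        X, priors = random_instance(rng, int(n), int(p), int(K))
        cfg = FactorizationConfig(
            K=int(K),
            lambda_lu=float(rng.random()),
            lambda_ru=float(rng.random()),
            lambda_lv=float(rng.random()),
            lambda_rv=float(rng.random()),
        )
        U = rng.random((int(n), int(K)))
        V = rng.random((int(p), int(K)))
        got = d.objective(X, U, V, priors, cfg)
        want = brute_force_objective(X, U, V, priors, cfg)
        assert got == pytest.approx(want, rel=1e-10)

    def test_shape_mismatch(self, rng):
        X, priors = random_instance(rng, 4, 5, 2)
        cfg = FactorizationConfig(K=2)
        with pytest.raises(ValueError, match="shape"):
            d.objective(X, np.ones((3, 2)), np.ones((5, 2)), priors, cfg)


class TestUpdates:
    def _scalar_system(self, x, u, v, **lam):
        X = np.array([[float(x)]])
        sample = d.similarity_from_correlation(np.array([[1.0]]))
        net = d.GeneNetwork(gene_ids=["g"], edges=set())
        gene = d.build_network_priors(net, ["g"])
        priors = d.PriorsBundle(sample=sample, gene=gene)
        zeros = dict(lambda_lu=0, lambda_ru=0, lambda_lv=0, lambda_rv=0)
        zeros.update(lam)
        cfg = FactorizationConfig(K=1, **zeros)
        return X, np.array([[float(u)]]), np.array([[float(v)]]), priors, cfg

    def test_u_hand_arithmetic(self):
        X, U, V, priors, cfg = self._scalar_system(2, 1, 1)
        assert d.update_u(X, U, V, priors, cfg)[0, 0] == pytest.approx(2.0)

    def test_v_hand_arithmetic_with_sparsity(self):
        X, U, V, priors, cfg = self._scalar_system(1, 2, 1, lambda_rv=1.0)
        # V <- 1 * (X'U) / (V U'U + lambda_rv * E V) = 2 / (4 + 1)
        assert d.update_v(X, U, V, priors, cfg)[0, 0] == pytest.approx(0.4)

    def test_zero_entries_stay_zero(self, rng):
        X, priors = random_instance(rng, 6, 8, 3)
        cfg = FactorizationConfig(K=3)
        U = rng.random((6, 3))
        V = rng.random((8, 3))
        U[2, 1] = 0.0
        V[4, 0] = 0.0
        assert d.update_u(X, U, V, priors, cfg)[2, 1] == 0.0
        assert d.update_v(X, U, V, priors, cfg)[4, 0] == 0.0

    def test_nonnegativity_preserved(self, rng):
        X, priors = random_instance(rng, 6, 8, 3)
        cfg = FactorizationConfig(K=3)
        U = rng.random((6, 3))
        V = rng.random((8, 3))
        for _ in range(20):
            U = d.update_u(X, U, V, priors, cfg)
            V = d.update_v(X, U, V, priors, cfg)
        assert (U >= 0).all() and (V >= 0).all()

    def test_fixed_point_unchanged(self, rng):
        # at num == den the multiplicative factor is 1 (up to the eps guard)
        X, priors = random_instance(rng, 5, 6, 2)
        cfg = dataclasses.replace(
            FactorizationConfig(K=2), tol=1e-12, max_iter=4000
        )
        model = d.CoRegularizedNMF(X, priors, cfg)
        res = model.fit()
        U2 = d.update_u(X, res.U, res.V, priors, cfg)
        np.testing.assert_allclose(U2, res.U, rtol=1e-4, atol=1e-9)

    def test_lambda_zero_matches_lee_seung_step(self, rng):
        X, priors = random_instance(rng, 7, 9, 3)
        cfg = FactorizationConfig(
            K=3, lambda_lu=0, lambda_ru=0, lambda_lv=0, lambda_rv=0
        )
        U = rng.random((7, 3))
        V = rng.random((9, 3))
        U1 = d.update_u(X, U, V, priors, cfg)
        V1 = d.update_v(X, U1, V, priors, cfg)
        U2, V2 = lee_seung_step(X, U, V, cfg.eps_guard)
        np.testing.assert_allclose(U1, U2, rtol=1e-12)
        np.testing.assert_allclose(V1, V2, rtol=1e-12)


class TestFit:
    def test_rank_one_all_ones_converges_to_zero(self):
        X = np.ones((3, 3))
        sample = d.similarity_from_correlation(np.ones((3, 3)))
        net = d.GeneNetwork(gene_ids=["a", "b", "c"], edges=set())
        priors = d.PriorsBundle(
            sample=sample, gene=d.build_network_priors(net, ["a", "b", "c"])
        )
        cfg = FactorizationConfig(
            K=1, lambda_lu=0, lambda_ru=0, lambda_lv=0, lambda_rv=0, tol=1e-10
        )
        res = d.CoRegularizedNMF(X, priors, cfg).fit()
        assert res.objective < 1e-4 * res.objective_trace[0]
        np.testing.assert_allclose(res.U @ res.V.T, X, atol=1e-2)

    def test_all_zero_matrix_collapses_u(self, rng):
        X, priors = random_instance(rng, 4, 5, 2)
        X = np.zeros_like(X)
        cfg = FactorizationConfig(K=2, lambda_lu=0, lambda_ru=0, lambda_lv=0, lambda_rv=0)
        U = rng.random((4, 2))
        V = rng.random((5, 2))
        U1 = d.update_u(X, U, V, priors, cfg)
        np.testing.assert_allclose(U1, 0.0, atol=1e-9)

    def test_determinism(self, rng):
        X, priors = random_instance(rng, 8, 10, 3)
        cfg = FactorizationConfig(K=3, seed=42, max_iter=50)
        r1 = d.CoRegularizedNMF(X, priors, cfg).fit()
        r2 = d.CoRegularizedNMF(X, priors, cfg).fit()
        assert np.array_equal(r1.U, r2.U)
        assert np.array_equal(r1.V, r2.V)
        assert np.array_equal(r1.objective_trace, r2.objective_trace)

    @pytest.mark.parametrize("variant", sorted(d.VARIANTS))
    def test_monotone_trace_all_variants(self, variant, rng):
        for seed in range(3):
            X, priors = random_instance(np.random.default_rng(seed), 8, 10, 3)
            cfg = make_variant_config(
                FactorizationConfig(K=3, seed=seed, max_iter=200), variant
            )
            res = d.CoRegularizedNMF(X, priors, cfg).fit()
            t = res.objective_trace
            assert np.all(t[1:] <= t[:-1] + 1e-9 * np.abs(t[:-1]))

    def test_lee_seung_full_trajectory(self, rng):
        X, priors = random_instance(rng, 8, 10, 3)
        cfg = FactorizationConfig(
            K=3, lambda_lu=0, lambda_ru=0, lambda_lv=0, lambda_rv=0,
            seed=5, max_iter=100, tol=1e-300,
        )
        gen = np.random.default_rng(5)
        U = gen.uniform(0.1, 1.1, size=(8, 3))
        V = gen.uniform(0.1, 1.1, size=(10, 3))
        for _ in range(100):
            U, V = lee_seung_step(X, U, V, cfg.eps_guard)
        res = d.CoRegularizedNMF(X, priors, cfg).fit()
        assert res.n_iter == 100
        np.testing.assert_allclose(res.U, U, rtol=1e-10)
        np.testing.assert_allclose(res.V, V, rtol=1e-10)

    def test_sparsity_response(self, tiny_aligned, tiny_priors):
        fractions = []
        for lam in (0.0, 1.0, 10.0):
            cfg = FactorizationConfig(lambda_rv=lam, seed=3, max_iter=400)
            res = d.fit(tiny_aligned, tiny_priors, cfg)
            thresh = 1e-6 * res.V.max()
            fractions.append(float((res.V < thresh).mean()))
        assert fractions[0] <= fractions[1] <= fractions[2]

    def test_eps_guard_insensitive(self, rng):
        X, priors = random_instance(rng, 8, 10, 3)
        base = FactorizationConfig(K=3, seed=1)
        res1 = d.CoRegularizedNMF(X, priors, base).fit()
        res2 = d.CoRegularizedNMF(
            X, priors, dataclasses.replace(base, eps_guard=2e-12)
        ).fit()
        assert res2.objective == pytest.approx(res1.objective, rel=1e-6)

    def test_dimension_checks(self, rng):
        X, priors = random_instance(rng, 6, 7, 2)
        with pytest.raises(ValueError, match="sample similarity"):
            d.CoRegularizedNMF(X[:4], priors)


class TestVariants:
    def test_mapping(self):
        base = FactorizationConfig()
        nop = make_variant_config(base, "no_prior")
        assert (nop.lambda_lu, nop.lambda_ru, nop.lambda_lv, nop.lambda_rv) == (0, 0, 0, 0)
        net = make_variant_config(base, "only_network")
        assert (net.lambda_lu, net.lambda_ru, net.lambda_lv, net.lambda_rv) == (0, 0, 1, 1)
        expr = make_variant_config(base, "only_expression")
        assert (expr.lambda_lu, expr.lambda_ru, expr.lambda_lv, expr.lambda_rv) == (1, 1, 0, 0)
        assert make_variant_config(base, "proposed") == base

    def test_unknown_variant(self):
        with pytest.raises(ValueError, match="unknown variant"):
            make_variant_config(FactorizationConfig(), "bogus")

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FactorizationConfig(K=0)
        with pytest.raises(ValueError):
            FactorizationConfig(lambda_lu=-0.1)


class TestSummary:
    def test_summary_mentions_fit_facts(self, tiny_aligned, tiny_priors):
        res = d.fit(tiny_aligned, tiny_priors, FactorizationConfig(max_iter=100))
        text = res.summary()
        assert "latent dims (K):    4" in text
        assert f"{res.n_iter}" in text
        assert "top genes" in text
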