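"""Variable-selection state: β conditional, index sets, γ moves, hyperpriors."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from sparsesur import covariance as cov
from sparsesur import graphs as gr
from sparsesur import selection as sel


def dense_setup(s):
    adj = ~np.eye(s, dtype=bool)
    jt = gr.build_junction_tree(adj)
    return adj, gr.perfect_elimination_order(jt)


def make_instance(rng, n, s, p, w=2.0):
    X = rng.standard_normal((n, p))
    A = rng.standard_normal((s, s))
    C = A @ A.T + s * np.eye(s)
    gamma = rng.random((s, p)) < 0.6
    beta = np.where(gamma, rng.standard_normal((s, p)), 0.0)
    Y = X @ beta.T + rng.standard_normal((n, s)) @ np.linalg.cholesky(C).T
    data = sel.Dataset(Y, X)
    state = sel.SelectionState(gamma, beta, w=w)
    rc = cov.decompose_covariance(C, np.arange(s))
    return data, state, rc, C


class TestIndexSets:
    def test_dense_s3(self):
        adj, peo = dense_setup(3)
        L, M, H = sel.index_sets(peo, adj, 1)
        assert L.tolist() == [0]
        assert M.tolist() == [2]
        assert H[2] == [0]

    def test_empty_graph_all_empty(self):
        s = 4
        jt = gr.build_junction_tree(np.zeros((s, s), dtype=bool))
        peo = gr.perfect_elimination_order(jt)
        for k in range(s):
            L, M, H = sel.index_sets(peo, jt.graph.adjacency, k)
            assert L.size == 0 and M.size == 0 and not H

    def test_chain_middle_node(self):
        """Chain 1-2-3: L(2)={1}, M(2)={3}, H(2,3)=∅ since node 1 is not in
        the prime {2,3}."""
        a = np.zeros((3, 3), dtype=bool)
        a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = True
        jt = gr.build_junction_tree(a)
        peo = gr.perfect_elimination_order(jt)
        L, M, H = sel.index_sets(peo, a, 1)
        assert L.tolist() == [0]
        assert M.tolist() == [2]
        assert H[2] == []

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_literal_prime_definition(self, seed):
        """Neighbour-based sets equal the literal 'share a prime component'
        definition on random chordal graphs."""
        from tests.test_graphs import random_chordal

        rng = np.random.default_rng(seed)
        a = random_chordal(7, rng)
        jt = gr.build_junction_tree(a)
        peo = gr.perfect_elimination_order(jt)
        pos = peo.position
        for k in range(7):
            L, M, H = sel.index_sets(peo, a, k)
            shares = {l for prime in jt.primes if k in prime for l in prime} - {k}
            assert set(L.tolist()) == {l for l in shares if pos[l] < pos[k]}
            assert set(M.tolist()) == {m for m in shares if pos[m] > pos[k]}
            for m in M:
                shares_m = {h for prime in jt.primes if m in prime for h in prime} - {m}
                assert set(H[m]) == {h for h in shares_m
                                     if pos[h] < pos[m] and h != k}


class TestLikelihood:
    def test_independent_limit(self):
        """ρ = 0, σ² = 1 reduces to independent Gaussian regressions."""
        rng = np.random.default_rng(0)
        data, state, _, _ = make_instance(rng, 12, 3, 4)
        adj, peo = dense_setup(3)
        rc = cov.ReparamCovariance(np.ones(3), np.zeros((3, 3)))
        got = sel.log_likelihood_factorised(data, state, rc, peo, adj)
        resid = data.Y - data.X @ state.beta.T
        expected = -0.5 * data.n * 3 * np.log(2 * np.pi) - 0.5 * np.sum(resid ** 2)
        assert got == pytest.approx(expected)

    def test_equals_matrix_normal_and_order_invariant(self):
        """The factorised likelihood equals the joint N(vec, C ⊗ I) density
        and is invariant to the decomposition ordering (dense case)."""
        rng = np.random.default_rng(1)
        for s, n in [(3, 10), (6, 20)]:
            data, state, rc, C = make_instance(rng, n, s, 4)
            adj, peo = dense_setup(s)
            got = sel.log_likelihood_factorised(data, state, rc, peo, adj)
            mean = (data.X @ state.beta.T).T.ravel()
            expected = multivariate_normal.logpdf(
                data.Y.T.ravel(), mean, np.kron(C, np.eye(n)))
            assert got == pytest.approx(expected)
            perm = rng.permutation(s)
            rc2 = cov.decompose_covariance(C, perm)
            peo2 = gr.PerfectEliminationOrder(perm, np.argsort(perm),
                                              np.zeros(s, int), np.zeros(s, int))
            got2 = sel.log_likelihood_factorised(data, state, rc2, peo2, adj)
            assert got2 == pytest.approx(expected)


class TestBetaConditional:
    @pytest.mark.parametrize("seed,s,p,n", [(0, 2, 3, 10), (1, 3, 4, 12), (2, 3, 2, 8)])
    def test_matches_brute_force_conditioning(self, seed, s, p, n):
        """Mean and precision of β_γk | rest equal brute-force Gaussian
        conditioning of the joint over all coefficient blocks."""
        rng = np.random.default_rng(seed)
        data, state, rc, C = make_instance(rng, n, s, p)
        adj, peo = dense_setup(s)
        Cinv = np.linalg.inv(C)
        idxs = [np.flatnonzero(state.gamma[k]) for k in range(s)]
        chi = np.zeros((n * s, sum(len(i) for i in idxs)))
        off = 0
        for k in range(s):
            chi[k * n:(k + 1) * n, off:off + len(idxs[k])] = data.X[:, idxs[k]]
            off += len(idxs[k])
        prec_big = np.kron(Cinv, np.eye(n))
        Lam = chi.T @ prec_big @ chi + np.eye(chi.shape[1]) / state.w
        bvec = chi.T @ prec_big @ data.Y.T.ravel()
        offs = np.cumsum([0] + [len(i) for i in idxs])
        beta_all = np.concatenate([state.beta[k, idxs[k]] for k in range(s)])
        for k in range(s):
            blk = slice(offs[k], offs[k + 1])
            others = np.r_[np.arange(offs[k]), np.arange(offs[k + 1], offs[-1])]
            mean_bf = np.linalg.solve(Lam[blk, blk],
                                      bvec[blk] - Lam[blk][:, others] @ beta_all[others])
            idx, mean, chol, logdet, _ = sel.beta_conditional_moments(
                k, data, state, rc, peo, adj)
            W = np.tril(chol[0]) @ np.tril(chol[0]).T
            assert np.abs(mean - mean_bf).max() < 1e-8
            assert np.abs(W - Lam[blk, blk]).max() < 1e-8

    def test_rho_zero_reduces_to_standard_conjugate(self):
        rng = np.random.default_rng(3)
        data, state, _, _ = make_instance(rng, 10, 2, 3)
        adj, peo = dense_setup(2)
        rc = cov.ReparamCovariance(np.array([2.0, 3.0]), np.zeros((2, 2)))
        k = 0
        idx, mean, chol, _, _ = sel.beta_conditional_moments(k, data, state, rc, peo, adj)
        Xg = data.X[:, idx]
        W = Xg.T @ Xg / rc.sigma2[k] + np.eye(idx.size) / state.w
        expected = np.linalg.solve(W, Xg.T @ data.Y[:, k] / rc.sigma2[k])
        assert np.allclose(mean, expected)

    def test_last_node_ytilde(self):
        """For the last-ordered node (M empty), ỹ_k = σ_k^{-2}(y_k − Σ ρ u)."""
        rng = np.random.default_rng(4)
        data, state, rc, _ = make_instance(rng, 9, 3, 3)
        adj, peo = dense_setup(3)
        k = 2
        scale, yt = sel._assemble_wtilde_ytilde(k, data, state, rc, peo, adj)
        U = data.Y - data.X @ state.beta.T
        expected = (data.Y[:, k] - U[:, :2] @ rc.rho[k, :2]) / rc.sigma2[k]
        assert np.allclose(yt, expected)
        assert scale == pytest.approx(1 / rc.sigma2[k])

    def test_empty_gamma_returns_empty(self):
        rng = np.random.default_rng(5)
        data, state, rc, _ = make_instance(rng, 8, 2, 3)
        state.gamma[0] = False
        adj, peo = dense_setup(2)
        idx, draw = sel.sample_beta_conditional(0, data, state, rc, peo, adj, rng)
        assert idx.size == 0 and draw.size == 0


class TestGammaMoves:
    def test_add_delete_ratio_consistency(self):
        """Forward add and reverse delete probabilities match analytically."""
        rng = np.random.default_rng(0)
        p = 6
        g = np.zeros(p, dtype=bool)
        new, logr = sel.propose_gamma(g, rng)
        assert new.sum() == 1
        # from |γ|=0, add is the only feasible move: q_fwd = 1/p;
        # reverse: from |γ|=1 all three moves feasible, delete picked w.p. 0.4
        assert logr == pytest.approx(np.log((0.4 / 1)) - np.log(1.0 / p))

    def test_swap_preserves_size(self):
        rng = np.random.default_rng(1)
        g = np.zeros(10, dtype=bool)
        g[:4] = True
        sizes = set()
        for _ in range(200):
            new, _ = sel.propose_gamma(g, rng)
            sizes.add(int(new.sum()))
        assert sizes <= {3, 4, 5}

    def test_prior_only_chain_recovers_beta_binomial(self):
        """Metropolis chain over γ_k with the beta-binomial prior matches the
        closed-form model-size law (p = 10, exact enumeration)."""
        rng = np.random.default_rng(2)
        p, a, b = 10, 1.5, 6.0
        # target: p(gamma) = Beta(a+|g|, b+p-|g|)/Beta(a,b) (o integrated out)
        from scipy.special import betaln

        def logp(g):
            m = int(g.sum())
            return betaln(a + m, b + p - m) - betaln(a, b)

        g = np.zeros(p, dtype=bool)
        sizes = []
        lp = logp(g)
        for it in range(60000):
            new, logr = sel.propose_gamma(g, rng)
            lp_new = logp(new)
            if np.log(rng.random()) < lp_new - lp + logr:
                g, lp = new, lp_new
            sizes.append(int(g.sum()))
        sizes = np.array(sizes[5000:])
        target = np.exp([sel.beta_binomial_logpmf(m, p, a, b) for m in range(p + 1)])
        emp = np.bincount(sizes, minlength=p + 1) / sizes.size
        batches = sizes[: (sizes.size // 50) * 50].reshape(50, -1)
        for m in range(p + 1):
            if target[m] < 5e-3:
                continue
            se = (batches == m).mean(axis=1).std(ddof=1) / np.sqrt(50)
            assert abs(emp[m] - target[m]) < 3 * se + 5e-3, (m, emp[m], target[m])


class TestGammaPrior:
    def test_all_zero(self):
        hot = sel.HotspotParams(np.array([0.1, 0.2]), np.array([1.0, 0.5, 2.0]),
                                a_o=1, b_o=1)
        gamma = np.zeros((2, 3), dtype=bool)
        expected = np.sum(np.log1p(-np.outer(hot.o, hot.pi)))
        assert sel.log_prior_gamma(gamma, hot) == pytest.approx(expected)

    def test_beta_binomial_matches_closed_form(self):
        """Integrating o_k ~ Beta(a,b) over the Bernoulli likelihood with
        π ≡ 1 gives the beta-binomial mass (Monte-Carlo integration)."""
        rng = np.random.default_rng(3)
        p, a, b = 8, 2.0, 10.0
        gamma = np.zeros((1, p), dtype=bool)
        gamma[0, :3] = True
        draws = rng.beta(a, b, size=40000)
        like = draws ** 3 * (1 - draws) ** (p - 3)
        mc = np.log(like.mean())
        from math import comb

        exact = sel.beta_binomial_logpmf(3, p, a, b) - np.log(comb(p, 3))
        assert mc == pytest.approx(exact, abs=0.02)

    def test_constraint_violation_raises(self):
        hot = sel.HotspotParams(np.array([0.9]), np.array([2.0]), a_o=1, b_o=1)
        with pytest.raises(ValueError):
            sel.log_prior_gamma(np.zeros((1, 1), dtype=bool), hot)


class TestHotspotUpdates:
    def test_betabinomial_conjugate_acceptance(self):
        """π ≡ 1: the o_k proposal is its exact conditional, so every
        in-constraint proposal is accepted."""
        rng = np.random.default_rng(4)
        gamma = rng.random((5, 20)) < 0.2
        hot = sel.HotspotParams(np.full(5, 0.1), np.ones(20), a_o=2.0, b_o=18.0,
                                variant="betabinomial")
        acc_o, _ = sel.update_hotspot_params(gamma, hot, rng)
        assert acc_o == 5
        # long-run mean matches Beta(a+|γ_k|, b+p−|γ_k|)
        means = np.zeros(5)
        reps = 4000
        for _ in range(reps):
            sel.update_hotspot_params(gamma, hot, rng)
            means += hot.o
        nk = gamma.sum(axis=1)
        target = (2.0 + nk) / (20.0 + 20)
        assert np.allclose(means / reps, target, atol=0.01)

    def test_hotspot_column_drives_pi_up(self):
        """A predictor associated with every response pulls E(π_j) above 1."""
        rng = np.random.default_rng(5)
        s, p = 8, 6
        gamma = np.zeros((s, p), dtype=bool)
        gamma[:, 0] = True
        hot = sel.HotspotParams(np.full(s, 0.2), np.ones(p), a_o=2.0, b_o=8.0,
                                a_pi=0.5, b_pi=0.5)
        acc = np.zeros(p)
        reps = 4000
        for _ in range(reps):
            sel.update_hotspot_params(gamma, hot, rng)
            acc += hot.pi
        mean_pi = acc / reps
        assert mean_pi[0] > 1.0
        assert np.all(mean_pi[1:] < mean_pi[0])

    def test_empty_column_stays_near_prior(self):
        rng = np.random.default_rng(6)
        gamma = np.zeros((4, 3), dtype=bool)
        hot = sel.HotspotParams(np.full(4, 0.05), np.ones(3), a_o=1.0, b_o=19.0,
                                a_pi=0.5, b_pi=0.5)
        acc = 0.0
        reps = 6000
        for _ in range(reps):
            sel.update_hotspot_params(gamma, hot, rng)
            acc += hot.pi[0]
        # Ga(1/2, 1/2) prior mean is 1; empty data pulls slightly below via
        # the (1 - o π) likelihood, never above
        assert acc / reps < 1.05


class TestWUpdate:
    def test_plug_in_conjugacy(self):
        """One included coefficient β = 2, a_w = b_w = 0.1 → IGa(0.6, 2.1)."""
        rng = np.random.default_rng(7)
        gamma = np.zeros((1, 2), dtype=bool)
        gamma[0, 0] = True
        beta = np.zeros((1, 2))
        beta[0, 0] = 2.0
        state = sel.SelectionState(gamma, beta, w=1.0, a_w=0.1, b_w=0.1)
        draws = np.array([sel.update_w(state, rng) for _ in range(40000)])
        # IGa(0.6, 2.1): E[1/w] = 0.6/2.1
        assert (1 / draws).mean() == pytest.approx(0.6 / 2.1, rel=0.03)

    def test_empty_gamma_prior_draw(self):
        rng = np.random.default_rng(8)
        state = sel.SelectionState(np.zeros((2, 3), dtype=bool), np.zeros((2, 3)),
                                   w=1.0, a_w=3.0, b_w=2.0)
        draws = np.array([sel.update_w(state, rng) for _ in range(20000)])
        assert draws.mean() == pytest.approx(2.0 / (3.0 - 1.0), rel=0.05)

    def test_support_invariant(self):
        rng = np.random.default_rng(9)
        gamma = rng.random((3, 5)) < 0.5
        beta = np.where(gamma, 1.0, 0.0)
        state = sel.SelectionState(gamma, beta)
        sel.update_w(state, rng)
        state.check()
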