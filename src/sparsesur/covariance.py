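"""Residual covariance reparametrisation C ↔ (σ², ρ) and its priors.

The s×s residual covariance ``C`` is encoded, given a node ordering, by the
sequential Schur-complement variances ``σ²_k`` and the regression coefficients
``ρ_k`` of response k's residual on the earlier residuals. Under a perfect
elimination order of a decomposable graph, ``ρ_k`` is supported on the
earlier-ordered neighbours of k only, and those structural zeros realise the
precision-matrix zeros of the graph without any completion step.

The transformed inverse-Wishart (dense) and hyper inverse-Wishart (sparse)
priors, the posterior conditionals given residuals, and the Metropolis update
of the scale hyperparameter τ live here. (σ², ρ) are nuisance state for the
sampler: only current values are kept, never traced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.linalg.lapack import dpotrf, dtrtrs
from scipy.special import gammaln

from .graphs import JunctionTree, PerfectEliminationOrder

__all__ = [
    "ReparamCovariance",
    "CovPriorParams",
    "decompose_covariance",
    "reconstruct_covariance",
    "log_prior_dense",
    "log_prior_sparse",
    "sample_prior",
    "sample_cov_conditional",
    "collapsed_cov_loglik",
    "update_tau",
]


@dataclass
class ReparamCovariance:
    """(σ², ρ) state. ``rho`` is an s×s matrix with rho[k, l] the coefficient
    of residual l in the regression for response k; entries off the support
    (non-neighbours, or later-ordered nodes) are exactly zero."""

    sigma2: np.ndarray
    rho: np.ndarray

    def copy(self) -> "ReparamCovariance":
        return ReparamCovariance(self.sigma2.copy(), self.rho.copy())


@dataclass
class CovPriorParams:
    """Hyperparameters of the (hyper) inverse-Wishart prior with M = τ I_s."""

    nu: float
    tau: float = 1.0
    a_tau: float = 0.1
    b_tau: float = 0.1

    def check(self, s: int) -> None:
        if self.nu <= s - 1:
            raise ValueError(f"nu must exceed s-1 = {s - 1}, got {self.nu}")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def _ordering_sets(order, adjacency=None):
    """L(k) for each node under ``order``: all earlier nodes (dense) or the
    earlier neighbours (sparse, given adjacency)."""
    order = np.asarray(order, dtype=int)
    s = order.size
    pos = np.empty(s, dtype=int)
    pos[order] = np.arange(s)
    sets = []
    for k in range(s):
        if adjacency is None:
            earlier = order[: pos[k]]
        else:
            earlier = np.asarray([l for l in np.flatnonzero(adjacency[k]) if pos[l] < pos[k]], dtype=int)
            earlier = earlier[np.argsort(pos[earlier])]
        sets.append(earlier)
    return sets


def _chol_with_jitter(a: np.ndarray):
    """Cholesky factor with a trace-scaled jitter retry on failure."""
    try:
        return cho_factor(a, lower=True)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * np.trace(a) / a.shape[0]
        import warnings

        warnings.warn("Cholesky failed; retrying with jitter", RuntimeWarning)
        return cho_factor(a + jitter * np.eye(a.shape[0]), lower=True)


def decompose_covariance(C: np.ndarray, order, adjacency=None) -> ReparamCovariance:
    """Schur-complement decomposition of an SPD matrix under ``order``.

    σ²_1 = C[o1,o1]; for later nodes σ²_k is the Schur complement of the
    covariance of L(k) and ρ_k = C_{L(k)}^{-1} c_k. With ``adjacency`` given,
    L(k) is restricted to earlier neighbours (valid when the ordering is a
    perfect elimination order of that graph).
    """
    C = np.asarray(C, dtype=float)
    s = C.shape[0]
    if not np.allclose(C, C.T, atol=1e-12):
        raise ValueError("C must be symmetric")
    try:
        np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("C must be positive-definite") from exc
    sets = _ordering_sets(order, adjacency)
    sigma2 = np.zeros(s)
    rho = np.zeros((s, s))
    for k in range(s):
        D = sets[k]
        if D.size == 0:
            sigma2[k] = C[k, k]
            continue
        chol = _chol_with_jitter(C[np.ix_(D, D)])
        r = cho_solve(chol, C[D, k])
        rho[k, D] = r
        sigma2[k] = C[k, k] - C[D, k] @ r
    return ReparamCovariance(sigma2, rho)


def reconstruct_covariance(rc: ReparamCovariance, order) -> np.ndarray:
    """Exact inverse of :func:`decompose_covariance` under the same ordering.

    Zero entries of ρ (the off-graph positions) propagate to exact zeros in
    the precision matrix of the result — conditional independences are
    realised implicitly by the recursion.
    """
    order = np.asarray(order, dtype=int)
    s = order.size
    C = np.zeros((s, s))
    for i, k in enumerate(order):
        prev = order[:i]
        if i == 0:
            C[k, k] = rc.sigma2[k]
            continue
        r = rc.rho[k, prev]
        cov = C[np.ix_(prev, prev)] @ r
        C[prev, k] = cov
        C[k, prev] = cov
        C[k, k] = rc.sigma2[k] + r @ cov
    return C


def _shape_k(nu: float, s: int, d: int) -> float:
    """IGa shape for a node with d earlier same-prime nodes: (ν − s + d + 1)/2."""
    return 0.5 * (nu - s + d + 1)


def _log_iga(x: float, a: float, b: float) -> float:
    return a * np.log(b) - gammaln(a) - (a + 1) * np.log(x) - b / x


def _transformed_logpdf(rc, sets, nu, s, M=None, tau=None):
    """Transformed (H)IW log density; scale matrix is tau*I when ``tau`` given."""
    total = 0.0
    for k in range(s):
        D = sets[k]
        d = D.size
        a = _shape_k(nu, s, d)
        sig = rc.sigma2[k]
        if tau is not None:
            b = 0.5 * tau
            total += _log_iga(sig, a, b)
            if d:
                r = rc.rho[k, D]
                total += (0.5 * d * np.log(tau) - 0.5 * d * np.log(2 * np.pi * sig)
                          - 0.5 * tau * (r @ r) / sig)
        else:
            MD = M[np.ix_(D, D)]
            mk = M[D, k]
            if d:
                chol = _chol_with_jitter(MD)
                sol = cho_solve(chol, mk)
                b = 0.5 * (M[k, k] - mk @ sol)
            else:
                sol = np.zeros(0)
                b = 0.5 * M[k, k]
            total += _log_iga(sig, a, b)
            if d:
                # ρ | σ² ~ N(M_DD^{-1} m_k, σ² M_DD^{-1})
                r = rc.rho[k, D] - sol
                quad = r @ (MD @ r)
                logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
                total += 0.5 * logdet - 0.5 * d * np.log(2 * np.pi * sig) - 0.5 * quad / sig
    return float(total)


def log_prior_dense(rc: ReparamCovariance, prior: CovPriorParams, order=None) -> float:
    """Transformed inverse-Wishart prior IW(ν, τI): independent per-k factors
    σ²_k ~ IGa((ν−s+k)/2, τ/2), ρ_k | σ²_k ~ N(0, (σ²_k/τ) I)."""
    s = rc.sigma2.size
    prior.check(s)
    if order is None:
        order = np.arange(s)
    sets = _ordering_sets(order)
    return _transformed_logpdf(rc, sets, prior.nu, s, tau=prior.tau)


def log_prior_sparse(rc: ReparamCovariance, jt: JunctionTree,
                     prior: CovPriorParams, peo: PerfectEliminationOrder) -> float:
    """Transformed hyper inverse-Wishart prior HIW_G(ν, τI) on (σ², ρ).

    Per node: σ²_k ~ IGa((ν − s + t + |S_q|)/2, τ/2) with t + |S_q| = |L(k)| + 1,
    ρ_k | σ²_k ~ N(0, (σ²_k/τ) I_{|L(k)|}) supported on earlier neighbours.
    """
    s = rc.sigma2.size
    prior.check(s)
    adj = jt.graph.adjacency
    sets = _ordering_sets(peo.order, adj)
    support = rc.rho != 0
    allowed = np.zeros((s, s), dtype=bool)
    for k in range(s):
        allowed[k, sets[k]] = True
    if np.any(support & ~allowed):
        raise ValueError("rho has support outside the graph's earlier-neighbour sets")
    return _transformed_logpdf(rc, sets, prior.nu, s, tau=prior.tau)


def sample_prior(jt_or_order, prior: CovPriorParams, rng, M: np.ndarray | None = None,
                 peo: PerfectEliminationOrder | None = None) -> ReparamCovariance:
    """Draw (σ², ρ) from the transformed prior.

    Pass a JunctionTree (with its perfect elimination order) for the sparse
    prior, or a plain ordering for the dense prior. ``M`` overrides the
    default scale τI (used by the synthetic-data G-Wishart sampler).
    """
    if isinstance(jt_or_order, JunctionTree):
        jt = jt_or_order
        if peo is None:
            from .graphs import perfect_elimination_order

            peo = perfect_elimination_order(jt)
        order = peo.order
        sets = _ordering_sets(order, jt.graph.adjacency)
        s = jt.graph.n_nodes
    else:
        order = np.asarray(jt_or_order, dtype=int)
        s = order.size
        sets = _ordering_sets(order)
    prior.check(s)
    sigma2 = np.zeros(s)
    rho = np.zeros((s, s))
    for k in range(s):
        D = sets[k]
        d = D.size
        a = _shape_k(prior.nu, s, d)
        if M is None:
            b = 0.5 * prior.tau
            mean = np.zeros(d)
            prec_chol = np.sqrt(prior.tau) * np.eye(d)
        else:
            MD = M[np.ix_(D, D)]
            mk = M[D, k]
            chol = _chol_with_jitter(MD) if d else None
            sol = cho_solve(chol, mk) if d else np.zeros(0)
            b = 0.5 * (M[k, k] - mk @ sol)
            mean = sol
        sig = 1.0 / rng.gamma(a, 1.0 / b)
        sigma2[k] = sig
        if d:
            z = rng.standard_normal(d)
            if M is None:
                rho[k, D] = mean + np.sqrt(sig / prior.tau) * z
            else:
                # covariance σ² M_DD^{-1} with M_DD = L Lᵀ: x solves Lᵀ x = z
                x = solve_triangular(chol[0], z, lower=chol[1], trans="T")
                rho[k, D] = mean + np.sqrt(sig) * x
    return ReparamCovariance(sigma2, rho)


def sample_cov_conditional(U: np.ndarray, jt_or_order, prior: CovPriorParams,
                           rng, n_eff: float | None = None,
                           peo: PerfectEliminationOrder | None = None) -> ReparamCovariance:
    """Gibbs draw of (σ², ρ) from the posterior conditionals given residuals U.

    σ²_k ~ IGa((n + ν − s + |L(k)| + 1)/2, (m̃_k − m̃ᵀ M̃_L^{-1} m̃)/2) and
    ρ_k | σ²_k ~ N(M̃_L^{-1} m̃, σ²_k M̃_L^{-1}) with M̃ = τI + UᵀU, using
    within-prime (earlier-neighbour) submatrices only. With an empty data
    matrix this reduces exactly to a prior draw.
    """
    if isinstance(jt_or_order, JunctionTree):
        jt = jt_or_order
        if peo is None:
            from .graphs import perfect_elimination_order

            peo = perfect_elimination_order(jt)
        order = peo.order
        sets = _ordering_sets(order, jt.graph.adjacency)
    else:
        order = np.asarray(jt_or_order, dtype=int)
        sets = _ordering_sets(order)
    s = order.size
    prior.check(s)
    n = U.shape[0] if n_eff is None else float(n_eff)
    Mt = U.T @ U + prior.tau * np.eye(s)
    sigma2 = np.zeros(s)
    rho = np.zeros((s, s))
    for k in range(s):
        D = sets[k]
        d = D.size
        a = 0.5 * n + _shape_k(prior.nu, s, d)
        if d:
            MD = Mt[D][:, D]
            L, info = dpotrf(MD, lower=1, overwrite_a=1, clean=1)
            if info != 0:
                L, info = dpotrf(MD + 1e-10 * np.trace(MD) / d * np.eye(d),
                                 lower=1, clean=1)
                if info != 0:
                    raise np.linalg.LinAlgError("M-tilde submatrix not SPD")
            half, _ = dtrtrs(L, Mt[D, k], lower=1)
            sol, _ = dtrtrs(L, half, lower=1, trans=1)
            b = 0.5 * (Mt[k, k] - half @ half)
        else:
            sol = np.zeros(0)
            b = 0.5 * Mt[k, k]
        sig = 1.0 / rng.gamma(a, 1.0 / b)
        sigma2[k] = sig
        if d:
            z = rng.standard_normal(d)
            x, _ = dtrtrs(L, z, lower=1, trans=1)
            rho[k, D] = sol + np.sqrt(sig) * x
    return ReparamCovariance(sigma2, rho)


def collapsed_cov_loglik(U: np.ndarray, jt_or_order, prior: CovPriorParams,
                         n_eff: float | None = None,
                         peo: PerfectEliminationOrder | None = None,
                         per_node: bool = False):
    """log ∫ Π_k N(u_k | U_L ρ_k, σ²_k I) p(σ², ρ | J, τ) d(σ², ρ).

    The (σ², ρ)-collapsed likelihood of the residual matrix given the graph;
    this is the only likelihood term entering the joint {J, σ², ρ}
    Metropolis-Hastings acceptance (implicit marginalisation: neither the
    current nor the proposed (σ², ρ) densities are ever evaluated).
    """
    if isinstance(jt_or_order, JunctionTree):
        jt = jt_or_order
        if peo is None:
            from .graphs import perfect_elimination_order

            peo = perfect_elimination_order(jt)
        order = peo.order
        sets = _ordering_sets(order, jt.graph.adjacency)
    else:
        order = np.asarray(jt_or_order, dtype=int)
        sets = _ordering_sets(order)
    s = order.size
    n = U.shape[0] if n_eff is None else float(n_eff)
    Mt = U.T @ U + prior.tau * np.eye(s)
    terms = _collapsed_terms(Mt, sets, prior.nu, prior.tau, n)
    return terms if per_node else float(terms.sum())


def _collapsed_terms(Mt, sets, nu, tau, n, nodes=None, out=None):
    """Per-node collapsed marginal terms given M̃ = τI + UᵀU and the L sets.

    Each term depends on L(k) only as a set, so totals are invariant to the
    particular perfect elimination order. ``nodes`` restricts recomputation
    (incremental updates after a graph move); results go into ``out``.
    """
    s = Mt.shape[0]
    terms = np.zeros(s) if out is None else out
    for k in (range(s) if nodes is None else nodes):
        D = sets[k]
        d = D.size
        a = _shape_k(nu, s, d)
        if d:
            MD = Mt[D][:, D]
            L, info = dpotrf(MD, lower=1, overwrite_a=1, clean=1)
            if info != 0:
                L, info = dpotrf(MD + 1e-10 * np.trace(MD) / d * np.eye(d),
                                 lower=1, clean=1)
            sol, _ = dtrtrs(L, Mt[D, k], lower=1)
            r = Mt[k, k] - sol @ sol
            logdet = 2.0 * np.sum(np.log(np.diag(L)))
        else:
            r = Mt[k, k]
            logdet = 0.0
        terms[k] = (
            -0.5 * n * np.log(2 * np.pi)
            + 0.5 * d * np.log(tau)
            - 0.5 * logdet
            + a * np.log(0.5 * tau)
            - gammaln(a)
            + gammaln(a + 0.5 * n)
            - (a + 0.5 * n) * np.log(0.5 * r)
        )
    return terms


def update_tau(rc: ReparamCovariance, jt_or_order, prior: CovPriorParams, rng,
               step: float = 0.5, peo: PerfectEliminationOrder | None = None):
    """Metropolis update of τ (log-scale random walk).

    Target: Ga(a_τ, b_τ) prior times the transformed (H)IW density of the
    current (σ², ρ). Returns (new_tau, accepted).
    """
    if isinstance(jt_or_order, JunctionTree):
        if peo is None:
            from .graphs import perfect_elimination_order

            peo = perfect_elimination_order(jt_or_order)
        sets = _ordering_sets(peo.order, jt_or_order.graph.adjacency)
        s = jt_or_order.graph.n_nodes
    else:
        order = np.asarray(jt_or_order, dtype=int)
        sets = _ordering_sets(order)
        s = order.size

    def logpost(tau):
        total = (prior.a_tau - 1.0) * np.log(tau) - prior.b_tau * tau
        for k in range(s):
            d = sets[k].size
            a = _shape_k(prior.nu, s, d)
            sig = rc.sigma2[k]
            total += a * np.log(0.5 * tau) - 0.5 * tau / sig
            if d:
                r = rc.rho[k, sets[k]]
                total += 0.5 * d * np.log(tau) - 0.5 * tau * (r @ r) / sig
        return total

    cur = prior.tau
    prop = cur * np.exp(step * rng.standard_normal())
    # log-scale proposal: symmetric in log tau, Jacobian gives + log(prop/cur)
    log_alpha = logpost(prop) - logpost(cur) + np.log(prop) - np.log(cur)
    if np.log(rng.random()) < log_alpha:
        return float(prop), True
    return float(cur), False
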