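"""Spike-and-slab variable selection for the factorised SUR likelihood.

Holds the binary inclusion matrix γ (s×p), the coefficient matrix β with
support(β) ⊆ support(γ), the slab precision w^{-1}, and the hotspot prior
γ_kj ~ Bernoulli(o_k · π_j): o_k is the per-response sparsity level and π_j a
per-predictor propensity shared across responses (π_j ≡ 1 recovers a
beta-binomial prior per response).

The key operation is the full conditional of the nonzero coefficients β_γk,
which accounts for the feedback of response k's residual on the later-ordered
responses in the same prime component of the residual graph, and its
β-collapsed marginal used by the joint {γ_k, β_γk} Metropolis-Hastings update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg.lapack import dpotrf, dtrtrs

__all__ = [
    "Dataset",
    "SelectionState",
    "HotspotParams",
    "index_sets",
    "log_likelihood_factorised",
    "beta_conditional_moments",
    "sample_beta_conditional",
    "collapsed_beta_marginal",
    "propose_gamma",
    "log_prior_gamma",
    "update_hotspot_params",
    "update_w",
]


@dataclass
class Dataset:
    """Response matrix Y (n×s) and shared predictor matrix X (n×p)."""

    Y: np.ndarray
    X: np.ndarray

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.Y.ndim != 2 or self.X.ndim != 2:
            raise ValueError("Y and X must be 2-D")
        if self.Y.shape[0] != self.X.shape[0]:
            raise ValueError(
                f"sample count mismatch: Y has {self.Y.shape[0]} rows, X has {self.X.shape[0]}"
            )
        if not (np.isfinite(self.Y).all() and np.isfinite(self.X).all()):
            raise ValueError("Y and X must be finite (missing values are not supported)")

    @property
    def n(self):
        return self.Y.shape[0]

    @property
    def s(self):
        return self.Y.shape[1]

    @property
    def p(self):
        return self.X.shape[1]


@dataclass
class SelectionState:
    """γ, β and the slab variance w. support(β) ⊆ support(γ) always."""

    gamma: np.ndarray  # s×p bool
    beta: np.ndarray   # s×p float, zero off gamma
    w: float = 1.0
    a_w: float = 0.1
    b_w: float = 0.1

    def check(self):
        assert self.w > 0
        assert not np.any((self.beta != 0) & ~self.gamma), "beta support exceeds gamma"


@dataclass
class HotspotParams:
    """Hotspot prior parameters; ``variant`` is 'hotspot' or 'betabinomial'."""

    o: np.ndarray                     # length s, in (0,1)
    pi: np.ndarray                    # length p, positive; all 1 for betabinomial
    a_o: float
    b_o: float
    a_pi: float = 0.5
    b_pi: float = 0.5
    variant: str = "hotspot"

    def check(self):
        assert np.all((self.o > 0) & (self.o < 1))
        if self.variant == "betabinomial":
            assert np.all(self.pi == 1.0)
        assert float(np.max(self.o)) * float(np.max(self.pi)) <= 1.0 + 1e-12, \
            "constraint o_k * pi_j <= 1 violated"


def index_sets(peo, adjacency, k: int):
    """(L, M, H) index sets for response k under the perfect elimination order.

    L(k): earlier-ordered nodes sharing a prime with k; M(k): later-ordered
    nodes sharing a prime; H(k, m) for m ∈ M(k): nodes earlier than m, other
    than k, sharing a prime with m. Sharing a prime is equivalent to
    adjacency, so the sets are earlier/later neighbour sets. The dense case
    is the complete graph (L = {earlier}, M = {later}).
    """
    pos = peo.position
    nb = np.flatnonzero(adjacency[k])
    L = sorted((int(l) for l in nb if pos[l] < pos[k]), key=lambda l: pos[l])
    M = sorted((int(m) for m in nb if pos[m] > pos[k]), key=lambda m: pos[m])
    H = {}
    for m in M:
        nbm = np.flatnonzero(adjacency[m])
        H[m] = sorted((int(h) for h in nbm if pos[h] < pos[m] and h != k),
                      key=lambda h: pos[h])
    return np.asarray(L, dtype=int), np.asarray(M, dtype=int), H


def log_likelihood_factorised(data: Dataset, state: SelectionState, rc, peo,
                              adjacency) -> float:
    """Σ_k log N(y_k | X_γk β_γk + U_L ρ_k, σ²_k I_n) under the ordering.

    Equals the joint matrix-normal log density of Y with the covariance
    reconstructed from (σ², ρ) — the factorisation is chain conditioning.
    """
    Y, X = data.Y, data.X
    n = data.n
    U = Y - X @ state.beta.T
    # rho rows are supported on earlier-ordered neighbours only, so the
    # regression term for every response is one matrix product
    resid = U - U @ rc.rho.T
    sig = rc.sigma2
    ss = np.einsum("ij,ij->j", resid, resid)
    return float(np.sum(-0.5 * n * np.log(2 * np.pi * sig) - 0.5 * ss / sig))


def _assemble_wtilde_ytilde(k, data, state, rc, peo, adjacency, U=None):
    """Scalar precision multiplier and working response ỹ_k of the β_γk
    conditional:

    W̃_k = X_γkᵀ X_γk (1/σ²_k + Σ_{m∈M} ρ²_mk/σ²_m) + w^{-1} I
    ỹ_k = σ_k^{-2}(y_k − Σ_{l∈L} ρ_kl u_l)
          − Σ_{m∈M} (ρ_mk/σ²_m)(u_m − Σ_{h∈H(k,m)} ρ_mh u_h − ρ_mk y_k)
    """
    Y, X = data.Y, data.X
    if U is None:
        U = Y - X @ state.beta.T
    L, M, H = index_sets(peo, adjacency, k)
    sig = rc.sigma2
    scale = 1.0 / sig[k]
    y = Y[:, k]
    yt = (y - (U[:, L] @ rc.rho[k, L] if L.size else 0.0)) / sig[k]
    for m in M:
        rmk = rc.rho[m, k]
        if rmk == 0.0:
            continue
        scale += rmk * rmk / sig[m]
        h = H[m]
        corr = U[:, m] - (U[:, h] @ rc.rho[m, h] if len(h) else 0.0) - rmk * y
        yt = yt - (rmk / sig[m]) * corr
    return scale, yt


def beta_conditional_moments(k, data, state, rc, peo, adjacency, gram=None,
                             gamma_k=None, scale_yt=None):
    """Mean and precision Cholesky of β_γk | rest ~ N(W̃^{-1} X_γᵀ ỹ, W̃^{-1}).

    Returns (idx, mean, chol_of_precision, logdet_prec, quad) where
    quad = bᵀ W̃^{-1} b with b = X_γkᵀ ỹ_k (reused by the collapsed marginal).
    ``scale_yt`` lets callers reuse the (W̃ multiplier, ỹ_k) pair across the
    current and proposed γ_k, which share it.
    """
    gamma_k = state.gamma[k] if gamma_k is None else gamma_k
    idx = np.flatnonzero(gamma_k)
    if scale_yt is None:
        scale_yt = _assemble_wtilde_ytilde(k, data, state, rc, peo, adjacency)
    scale, yt = scale_yt
    if idx.size == 0:
        return idx, np.zeros(0), None, 0.0, 0.0
    Xg = data.X[:, idx]
    XtX = gram[idx][:, idx] if gram is not None else Xg.T @ Xg
    W = XtX * scale + (1.0 / state.w) * np.eye(idx.size)
    b = Xg.T @ yt
    L, info = dpotrf(W, lower=1, overwrite_a=1, clean=1)
    if info != 0:
        raise np.linalg.LinAlgError("W-tilde not positive definite")
    half, _ = dtrtrs(L, b, lower=1)
    mean, _ = dtrtrs(L, half, lower=1, trans=1)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    quad = float(half @ half)
    return idx, mean, (L, True), logdet, quad


def sample_beta_conditional(k, data, state, rc, peo, adjacency, rng,
                            gram=None, gamma_k=None, scale_yt=None):
    """Draw β_γk from its full conditional; empty γ_k returns an empty vector."""
    idx, mean, chol, _, _ = beta_conditional_moments(
        k, data, state, rc, peo, adjacency, gram=gram, gamma_k=gamma_k,
        scale_yt=scale_yt)
    if idx.size == 0:
        return idx, np.zeros(0)
    z = rng.standard_normal(idx.size)
    x, _ = dtrtrs(chol[0], z, lower=1, trans=1)
    return idx, mean + x


def collapsed_beta_marginal(k, data, state, rc, peo, adjacency, gram=None,
                            gamma_k=None, scale_yt=None) -> float:
    """log ∫ (likelihood factors in β_k) N(β | 0, w I) dβ, up to terms that do
    not depend on γ_k: −(|γ_k|/2) log w − ½ log|W̃| + ½ bᵀW̃^{-1}b.

    Used in the joint {γ_k, β_γk} acceptance ratio (implicit
    marginalisation); the proposed and current β densities are never
    evaluated.
    """
    gamma_k = state.gamma[k] if gamma_k is None else gamma_k
    idx, _, _, logdet, quad = beta_conditional_moments(
        k, data, state, rc, peo, adjacency, gram=gram, gamma_k=gamma_k,
        scale_yt=scale_yt)
    return -0.5 * idx.size * np.log(state.w) - 0.5 * logdet + 0.5 * quad


# ---------------------------------------------------------------------------
# γ moves and priors
# ---------------------------------------------------------------------------

_MOVE_WEIGHTS = {"add": 0.4, "delete": 0.4, "swap": 0.2}


def _feasible_moves(size, p):
    moves = []
    if size < p:
        moves.append("add")
    if size > 0:
        moves.append("delete")
    if 0 < size < p:
        moves.append("swap")
    return moves


def _move_prob(move, size, p):
    feas = _feasible_moves(size, p)
    tot = sum(_MOVE_WEIGHTS[m] for m in feas)
    return _MOVE_WEIGHTS[move] / tot if move in feas else 0.0


def propose_gamma(gamma_k: np.ndarray, rng):
    """One local add/delete/swap move on γ_k with its exact log proposal ratio.

    Between-chain exchange moves are handled by the tempered ensemble in the
    engine; this function covers the within-chain local move family.
    Returns (gamma_star, log q(γ|γ*) − log q(γ*|γ)).
    """
    p = gamma_k.size
    size = int(gamma_k.sum())
    feas = _feasible_moves(size, p)
    if not feas:
        raise ValueError("no feasible move (p == 0)")
    weights = np.array([_MOVE_WEIGHTS[m] for m in feas])
    move = feas[int(rng.choice(len(feas), p=weights / weights.sum()))]
    new = gamma_k.copy()
    ones = np.flatnonzero(gamma_k)
    zeros = np.flatnonzero(~gamma_k)
    if move == "add":
        j = int(zeros[rng.integers(zeros.size)])
        new[j] = True
        q_fwd = _move_prob("add", size, p) / zeros.size
        q_rev = _move_prob("delete", size + 1, p) / (size + 1)
    elif move == "delete":
        j = int(ones[rng.integers(ones.size)])
        new[j] = False
        q_fwd = _move_prob("delete", size, p) / ones.size
        q_rev = _move_prob("add", size - 1, p) / (p - size + 1)
    else:  # swap: |γ| preserved
        j0 = int(ones[rng.integers(ones.size)])
        j1 = int(zeros[rng.integers(zeros.size)])
        new[j0] = False
        new[j1] = True
        q_fwd = _move_prob("swap", size, p) / (ones.size * zeros.size)
        q_rev = q_fwd
    return new, float(np.log(q_rev) - np.log(q_fwd))


def log_prior_gamma(gamma: np.ndarray, hot: HotspotParams) -> float:
    """Σ_kj γ_kj log(o_k π_j) + (1−γ_kj) log(1−o_k π_j)."""
    prob = np.outer(hot.o, hot.pi)
    if np.any(prob > 1.0 + 1e-12):
        raise ValueError("constraint o_k * pi_j <= 1 violated")
    prob = np.clip(prob, 1e-300, 1.0)
    g = gamma.astype(float)
    return float(np.sum(g * np.log(prob) + (1.0 - g) * np.log1p(-np.clip(prob, 0, 1 - 1e-15))))


def _bern_loglik(gamma, o, pi):
    """Per-(k,j) Bernoulli(o_k π_j) log likelihood, summed over j (rows) or
    k (columns) by the caller."""
    prob = np.clip(np.outer(o, pi), 1e-300, 1 - 1e-15)
    return np.where(gamma, np.log(prob), np.log1p(-prob))


def _beta_logpdf(x, a, b):
    from scipy.special import betaln

    return (a - 1) * np.log(x) + (b - 1) * np.log1p(-x) - betaln(a, b)


def update_hotspot_params(gamma: np.ndarray, hot: HotspotParams, rng,
                          pi_steps: np.ndarray | None = None):
    """Metropolis updates of o (per response) and π (per predictor).

    o_k uses an independence proposal from Beta(a_o + |γ_k|, b_o + p − |γ_k|)
    — exact conjugacy (acceptance 1) in the beta-binomial variant. π_j uses a
    log-scale random walk against its Gamma prior. Proposals violating
    o_k·π_j ≤ 1 are rejected outright. Mutates ``hot``; returns acceptance
    counts (n_acc_o, n_acc_pi). The per-k and per-j updates are independent
    given the other block, so they are carried out in a vectorised pass.
    """
    s, p = gamma.shape
    pimax = float(np.max(hot.pi))
    nk = gamma.sum(axis=1)
    a_post, b_post = hot.a_o + nk, hot.b_o + p - nk
    prop_o = rng.beta(a_post, b_post)
    ok_mask = prop_o * pimax <= 1.0
    if hot.variant == "betabinomial":
        hot.o[ok_mask] = prop_o[ok_mask]
        acc_o = int(ok_mask.sum())
    else:
        cur = hot.o
        log_alpha = (
            _bern_loglik(gamma, prop_o, hot.pi).sum(axis=1)
            - _bern_loglik(gamma, cur, hot.pi).sum(axis=1)
            + _beta_logpdf(prop_o, hot.a_o, hot.b_o) - _beta_logpdf(cur, hot.a_o, hot.b_o)
            + _beta_logpdf(cur, a_post, b_post) - _beta_logpdf(prop_o, a_post, b_post)
        )
        accept = ok_mask & (np.log(rng.random(s)) < log_alpha)
        hot.o[accept] = prop_o[accept]
        acc_o = int(accept.sum())
    acc_pi = 0
    if hot.variant == "hotspot":
        omax = float(np.max(hot.o))
        steps = np.full(p, 0.5) if pi_steps is None else pi_steps
        cur = hot.pi
        prop = cur * np.exp(steps * rng.standard_normal(p))
        ok_mask = prop * omax <= 1.0
        log_alpha = (
            _bern_loglik(gamma, hot.o, prop).sum(axis=0)
            - _bern_loglik(gamma, hot.o, cur).sum(axis=0)
            + (hot.a_pi - 1) * (np.log(prop) - np.log(cur))
            - hot.b_pi * (prop - cur)
            + np.log(prop) - np.log(cur)  # log-scale proposal Jacobian
        )
        accept = ok_mask & (np.log(rng.random(p)) < log_alpha)
        hot.pi[accept] = prop[accept]
        acc_pi = int(accept.sum())
    return acc_o, acc_pi


def update_w(state: SelectionState, rng) -> float:
    """Conjugate draw w ~ IGa(a_w + |γ|/2, b_w + Σ β²/2) over included cells."""
    ngam = int(state.gamma.sum())
    ssq = float(np.sum(state.beta[state.gamma] ** 2))
    a = state.a_w + 0.5 * ngam
    b = state.b_w + 0.5 * ssq
    state.w = float(1.0 / rng.gamma(a, 1.0 / b))
    return state.w


def beta_binomial_logpmf(m: int, p: int, a: float, b: float) -> float:
    """Closed-form log P(|γ_k| = m) under o_k ~ Beta(a,b), π ≡ 1 (oracle use)."""
    from math import comb, lgamma

    def lbeta(x, y):
        return lgamma(x) + lgamma(y) - lgamma(x + y)

    return np.log(comb(p, m)) + lbeta(a + m, b + p - m) - lbeta(a, b)
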