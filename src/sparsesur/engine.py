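"""MCMC orchestration for the reparametrised sparse SUR model.

One sweep follows the sampler's update schedule: (1) joint Metropolis-Hastings
moves on {junction tree, σ², ρ} using the (σ², ρ)-collapsed residual
likelihood (implicit marginalisation) followed by a Gibbs refresh of (σ², ρ);
(2) per-response joint {γ_k, β_γk} updates, again collapsed over β; (3)
Metropolis updates of the hotspot parameters o_k and π_j; (4) Gibbs/Metropolis
updates of w, τ and η.

A small tempered ensemble (evolutionary-stochastic-search style) runs the
same sweep on likelihood-tempered copies of the data — temperature T is
implemented exactly as the scaling (X, Y) → (X, Y)/√T with effective sample
size n/T — and exchanges whole states between adjacent temperatures. Only the
cold chain contributes to posterior summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from . import covariance as cov
from . import graphs as gr
from . import selection as sel
from .summaries import PosteriorSummary

logger = logging.getLogger("sparsesur")

__all__ = ["RunConfig", "ChainState", "run_chain", "graph_cov_update", "gamma_beta_update"]


@dataclass
class RunConfig:
    """Chain settings and prior hyperparameters.

    ``a_o``/``b_o`` default to a prior model size of mean ~2 per response
    (a_o = 2, b_o = p − 2), matching a strongly sparse regression prior;
    ``nu`` defaults to s + 2 (finite prior covariance mean).
    """

    n_iter: int = 10000
    burnin: int | None = None          # default: 20% of n_iter
    thin: int = 10
    covariance: str = "sparse"         # 'sparse' | 'dense'
    n_chains: int = 2
    variant: str = "hotspot"           # 'hotspot' | 'betabinomial'
    graph_moves_per_sweep: int = 5
    seed: int = 0
    # prior hyperparameters (None -> data-dependent default)
    a_o: float | None = None
    b_o: float | None = None
    a_pi: float = 0.5
    b_pi: float = 0.5
    a_w: float = 0.1
    b_w: float = 0.1
    a_tau: float = 0.1
    b_tau: float = 0.1
    a_eta: float = 1.0
    b_eta: float = 1.0
    nu: float | None = None
    temperature: float = 2.0           # initial hot-chain temperature
    adapt_exchange_target: float = 0.25
    full_trace: bool = False           # keep the thinned γ trace (cross-check mode)

    def resolved(self, s: int, p: int) -> "RunConfig":
        out = replace(self)
        if out.burnin is None:
            out.burnin = out.n_iter // 5
        if out.burnin >= out.n_iter:
            raise ValueError("burnin must be smaller than n_iter")
        if out.a_o is None:
            out.a_o = 2.0
        if out.b_o is None:
            out.b_o = max(float(p) - 2.0, 2.0)
        if out.nu is None:
            out.nu = float(s) + 2.0
        if out.covariance not in ("sparse", "dense"):
            raise ValueError("covariance must be 'sparse' or 'dense'")
        if out.variant not in ("hotspot", "betabinomial"):
            raise ValueError("variant must be 'hotspot' or 'betabinomial'")
        return out


@dataclass
class ChainState:
    """Full parameter state of one chain (at one temperature)."""

    data: sel.Dataset              # temperature-scaled view of (Y, X)
    n_eff: float                   # n / T
    temperature: float
    jt: gr.JunctionTree | None     # None in dense mode
    peo: gr.PerfectEliminationOrder
    adjacency: np.ndarray          # complete graph in dense mode
    rc: cov.ReparamCovariance
    state: sel.SelectionState
    hot: sel.HotspotParams
    cov_prior: cov.CovPriorParams
    eta: float
    U: np.ndarray                  # residuals of the scaled data
    gram: np.ndarray               # XᵀX of the scaled predictors
    collapsed_cov: float | None = None   # cached Σ_k collapsed cov marginal

    def refresh_residuals(self) -> None:
        self.U = self.data.Y - self.data.X @ self.state.beta.T

    def loglik_unscaled(self, data_full: sel.Dataset) -> float:
        adj = self.adjacency
        return sel.log_likelihood_factorised(data_full, self.state, self.rc,
                                             self.peo, adj)


def _init_chain(data_full: sel.Dataset, config: RunConfig, temperature: float,
                rng) -> ChainState:
    n, s, p = data_full.n, data_full.s, data_full.p
    scale = 1.0 / np.sqrt(temperature)
    data = sel.Dataset(data_full.Y * scale, data_full.X * scale)
    sparse = config.covariance == "sparse"
    if sparse:
        jt = gr.build_junction_tree(np.zeros((s, s), dtype=bool))
        adjacency = jt.graph.adjacency
    else:
        jt = None
        adjacency = ~np.eye(s, dtype=bool)
        jt_dense = gr.build_junction_tree(adjacency)
    peo = gr.perfect_elimination_order(jt if sparse else jt_dense)
    cov_prior = cov.CovPriorParams(nu=config.nu, tau=1.0,
                                   a_tau=config.a_tau, b_tau=config.b_tau)
    rc = cov.ReparamCovariance(np.ones(s), np.zeros((s, s)))
    gamma = np.zeros((s, p), dtype=bool)
    beta = np.zeros((s, p))
    state = sel.SelectionState(gamma, beta, w=1.0, a_w=config.a_w, b_w=config.b_w)
    o0 = np.full(s, config.a_o / (config.a_o + config.b_o))
    pi0 = np.ones(p)
    hot = sel.HotspotParams(o0, pi0, config.a_o, config.b_o,
                            config.a_pi, config.b_pi, config.variant)
    eta = config.a_eta / (config.a_eta + config.b_eta)
    chain = ChainState(data=data, n_eff=n / temperature, temperature=temperature,
                       jt=jt, peo=peo, adjacency=adjacency, rc=rc, state=state,
                       hot=hot, cov_prior=cov_prior, eta=eta,
                       U=data.Y.copy(), gram=data.X.T @ data.X)
    return chain


def graph_cov_update(chain: ChainState, rng, n_moves: int = 1):
    """Joint {J*, σ²*, ρ*} Metropolis-Hastings step(s) plus Gibbs refresh.

    The acceptance ratio contains only the collapsed residual likelihood, the
    edge-count graph prior and the proposal ratio — by construction it never
    evaluates a (σ², ρ) density (implicit marginalisation). The identity
    proposal J* = J is accepted with probability one.
    """
    accepted = 0
    if chain.jt is not None:
        prior = chain.cov_prior
        Mt = chain.U.T @ chain.U + prior.tau * np.eye(chain.data.s)
        sets = gr.earlier_neighbour_sets(chain.adjacency, chain.peo)
        terms = cov._collapsed_terms(Mt, sets, prior.nu, prior.tau, chain.n_eff)
        for _ in range(n_moves):
            move = gr.propose_graph_move(chain.jt, rng)
            if move is None:
                continue
            jt_star, log_prop_ratio = move
            peo_star = gr.perfect_elimination_order(jt_star)
            sets_star = gr.earlier_neighbour_sets(jt_star.graph.adjacency, peo_star)
            # per-node terms depend on L(k) as a set only: recompute the
            # nodes whose earlier-neighbour set changed
            changed = [k for k in range(chain.data.s)
                       if sets[k].size != sets_star[k].size
                       or set(sets[k]) != set(sets_star[k])]
            terms_star = terms.copy()
            cov._collapsed_terms(Mt, sets_star, prior.nu, prior.tau,
                                 chain.n_eff, nodes=changed, out=terms_star)
            log_alpha = (
                float(terms_star.sum() - terms.sum())
                + gr.log_graph_prior(jt_star, chain.eta)
                - gr.log_graph_prior(chain.jt, chain.eta)
                + log_prop_ratio
            )
            if np.log(rng.random()) < log_alpha:
                chain.jt = jt_star
                chain.peo = peo_star
                chain.adjacency = jt_star.graph.adjacency
                sets, terms = sets_star, terms_star
                accepted += 1
        chain.collapsed_cov = float(terms.sum())
        chain.rc = cov.sample_cov_conditional(
            chain.U, chain.jt, chain.cov_prior, rng, n_eff=chain.n_eff, peo=chain.peo)
    else:
        # dense mode: the step is a pure Gibbs draw of (σ², ρ)
        chain.rc = cov.sample_cov_conditional(
            chain.U, chain.peo.order, chain.cov_prior, rng, n_eff=chain.n_eff)
    return accepted


def gamma_beta_update(chain: ChainState, k: int, rng):
    """Joint {γ*_k, β*_γk} Metropolis-Hastings update with implicit
    marginalisation over β. On rejection, γ_k, β_k and U are left untouched."""
    st = chain.state
    scale_yt = sel._assemble_wtilde_ytilde(
        k, chain.data, st, chain.rc, chain.peo, chain.adjacency, U=chain.U)
    gamma_star, log_prop_ratio = sel.propose_gamma(st.gamma[k], rng)
    cur = sel.collapsed_beta_marginal(
        k, chain.data, st, chain.rc, chain.peo, chain.adjacency,
        gram=chain.gram, scale_yt=scale_yt)
    prop = sel.collapsed_beta_marginal(
        k, chain.data, st, chain.rc, chain.peo, chain.adjacency,
        gram=chain.gram, gamma_k=gamma_star, scale_yt=scale_yt)
    probs = np.clip(chain.hot.o[k] * chain.hot.pi, 1e-300, 1 - 1e-15)
    changed = np.flatnonzero(st.gamma[k] != gamma_star)
    d_prior = 0.0
    for j in changed:
        term = np.log(probs[j]) - np.log1p(-probs[j])
        d_prior += term if gamma_star[j] else -term
    log_alpha = prop - cur + d_prior + log_prop_ratio
    if np.log(rng.random()) < log_alpha:
        idx, draw = sel.sample_beta_conditional(
            k, chain.data, st, chain.rc, chain.peo, chain.adjacency, rng,
            gram=chain.gram, gamma_k=gamma_star, scale_yt=scale_yt)
        st.gamma[k] = gamma_star
        st.beta[k] = 0.0
        st.beta[k, idx] = draw
        chain.U[:, k] = chain.data.Y[:, k] - chain.data.X @ st.beta[k]
        return True
    return False


def _sweep(chain: ChainState, config: RunConfig, rng, adapt: bool,
           tau_step: list, pi_steps: np.ndarray, counters: dict):
    s = chain.data.s
    acc_g = graph_cov_update(chain, rng, n_moves=config.graph_moves_per_sweep
                             if chain.jt is not None else 1)
    counters["graph_acc"] += acc_g
    counters["graph_prop"] += config.graph_moves_per_sweep if chain.jt is not None else 0
    for k in range(s):
        counters["gamma_acc"] += gamma_beta_update(chain, k, rng)
        counters["gamma_prop"] += 1
    acc_o, acc_pi = sel.update_hotspot_params(chain.state.gamma, chain.hot, rng,
                                              pi_steps=pi_steps)
    counters["o_acc"] += acc_o
    counters["pi_acc"] += acc_pi
    sel.update_w(chain.state, rng)
    jt_or_order = chain.jt if chain.jt is not None else chain.peo.order
    new_tau, acc_t = cov.update_tau(chain.rc, jt_or_order, chain.cov_prior, rng,
                                    step=tau_step[0], peo=chain.peo)
    chain.cov_prior.tau = new_tau
    counters["tau_acc"] += acc_t
    if adapt:
        tau_step[0] *= np.exp(0.02 * ((1.0 if acc_t else 0.0) - 0.44))
        tau_step[0] = float(np.clip(tau_step[0], 1e-3, 10.0))
    if chain.jt is not None:
        chain.eta = gr.gibbs_update_eta(chain.jt, config.a_eta, config.b_eta, rng)
    chain.collapsed_cov = None  # U/τ moved on; cache invalid


def run_chain(data, config: RunConfig | None = None, rng=None):
    """Run the full sampler and return a :class:`PosteriorSummary`.

    ``data`` is a Dataset (or (Y, X) pair). Deterministic given the seed in
    ``config`` (or the supplied generator).
    """
    if not isinstance(data, sel.Dataset):
        data = sel.Dataset(*data)
    if not (np.isfinite(data.Y).all() and np.isfinite(data.X).all()):
        raise ValueError("Y and X must be finite")
    config = (config or RunConfig()).resolved(data.s, data.p)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, s, p = data.n, data.s, data.p
    temps = [config.temperature ** i for i in range(config.n_chains)]
    chains = [_init_chain(data, config, t, rng) for t in temps]
    tau_steps = [[0.5] for _ in chains]
    pi_steps = [np.full(p, 0.5) for _ in chains]
    log_temp_gap = np.log(max(config.temperature, 1.0 + 1e-3) - 1.0 + 1e-12) \
        if config.n_chains > 1 else 0.0

    mpip = np.zeros((s, p))
    mepip = np.zeros((s, s))
    beta_mean = np.zeros((s, p))
    o_mean = np.zeros(s)
    pi_mean = np.zeros(p)
    n_acc = 0
    diagnostics = []
    gamma_trace = []
    counters = [dict(graph_acc=0, graph_prop=0, gamma_acc=0, gamma_prop=0,
                     o_acc=0, pi_acc=0, tau_acc=0) for _ in chains]
    exch_acc = exch_prop = 0

    for it in range(config.n_iter):
        adapt = it < config.burnin
        for ci, chain in enumerate(chains):
            _sweep(chain, config, rng, adapt, tau_steps[ci], pi_steps[ci],
                   counters[ci])
        if config.n_chains > 1:
            ci = int(rng.integers(config.n_chains - 1))
            c1, c2 = chains[ci], chains[ci + 1]
            ll1 = c1.loglik_unscaled(data)
            ll2 = c2.loglik_unscaled(data)
            delta = (1.0 / c1.temperature - 1.0 / c2.temperature) * (ll2 - ll1)
            exch_prop += 1
            acc = np.log(rng.random()) < delta
            if acc:
                _swap_states(c1, c2)
                exch_acc += 1
            if adapt and ci == 0 and config.n_chains == 2:
                log_temp_gap += 0.05 * ((1.0 if acc else 0.0) - config.adapt_exchange_target)
                new_t = 1.0 + np.exp(log_temp_gap)
                _retemper(chains[1], data, new_t)
        cold = chains[0]
        ll = cold.loglik_unscaled(data)
        if not np.isfinite(ll):
            raise RuntimeError(
                f"non-finite log-likelihood at iteration {it}: "
                f"|gamma|={int(cold.state.gamma.sum())}, tau={cold.cov_prior.tau}")
        if it >= config.burnin:
            mpip += cold.state.gamma
            beta_mean += cold.state.beta
            o_mean += cold.hot.o
            pi_mean += cold.hot.pi
            if cold.jt is not None:
                mepip += cold.adjacency
            n_acc += 1
            if config.full_trace and (it - config.burnin) % config.thin == 0:
                gamma_trace.append(cold.state.gamma.copy())
        if it % config.thin == 0:
            c = counters[0]
            diagnostics.append(dict(
                iteration=it, loglik=ll,
                n_gamma=int(cold.state.gamma.sum()),
                n_edges=cold.jt.n_graph_edges if cold.jt is not None else s * (s - 1) // 2,
                eta=cold.eta, tau=cold.cov_prior.tau, w=cold.state.w,
                gamma_acc_rate=c["gamma_acc"] / max(c["gamma_prop"], 1),
                graph_acc_rate=c["graph_acc"] / max(c["graph_prop"], 1),
            ))
        if (it + 1) % 1000 == 0:
            c = counters[0]
            logger.info("iter %d: loglik=%.2f |gamma|=%d |J|=%s acc(gamma)=%.3f",
                        it + 1, ll, int(cold.state.gamma.sum()),
                        cold.jt.n_graph_edges if cold.jt is not None else "-",
                        c["gamma_acc"] / max(c["gamma_prop"], 1))

    import pandas as pd

    summary = PosteriorSummary(
        mpip=mpip / n_acc,
        mepip=(mepip / n_acc + np.eye(s)) if config.covariance == "sparse" else np.ones((s, s)),
        pi_mean=pi_mean / n_acc,
        o_mean=o_mean / n_acc,
        beta_mean=beta_mean / n_acc,
        diagnostics=pd.DataFrame(diagnostics),
    )
    extras = dict(
        counters=counters,
        exchange_rate=exch_acc / max(exch_prop, 1),
        final_temperature=chains[-1].temperature,
        gamma_trace=np.asarray(gamma_trace) if config.full_trace else None,
        final_state=chains[0],
    )
    return summary, extras


def _swap_states(c1: ChainState, c2: ChainState):
    """Exchange full parameter states between two tempered chains."""
    for name in ("jt", "peo", "adjacency", "rc", "state", "hot", "eta"):
        a, b = getattr(c1, name), getattr(c2, name)
        setattr(c1, name, b)
        setattr(c2, name, a)
    t1, t2 = c1.cov_prior.tau, c2.cov_prior.tau
    c1.cov_prior.tau, c2.cov_prior.tau = t2, t1
    c1.refresh_residuals()
    c2.refresh_residuals()
    c1.collapsed_cov = None
    c2.collapsed_cov = None


def _retemper(chain: ChainState, data_full: sel.Dataset, new_t: float):
    scale = 1.0 / np.sqrt(new_t)
    chain.temperature = new_t
    chain.data = sel.Dataset(data_full.Y * scale, data_full.X * scale)
    chain.n_eff = data_full.n / new_t
    chain.gram = chain.data.X.T @ chain.data.X
    chain.refresh_residuals()
    chain.collapsed_cov = None
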