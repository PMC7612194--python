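"""Synthetic mQTL-style study designs for validating the sampler.

Two families:

* QTL scenarios — LD-structured genotype-like dosages, a chosen residual
  graph (block-diagonal / decomposable / non-decomposable), a G-Wishart
  precision on that graph, structured association patterns (hotspots,
  per-prime, per-residual, cross-component), N(5, 1) effects, and a
  signal-to-noise level for the predictors targeted within ±10% by scaling
  the G-Wishart scale matrix.
* Toeplitz scenarios — AR(0.7)-correlated Gaussian predictors, 20% of
  coefficient cells drawn Uniform(−2, 2), and banded Toeplitz inverse error
  covariances of increasing density.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import covariance as cov
from . import graphs as gr

__all__ = [
    "QtlScenario",
    "ToeplitzScenario",
    "QtlData",
    "make_genotype_like_predictors",
    "make_graph",
    "sample_precision_gwishart",
    "make_gamma_pattern",
    "simulate_qtl_scenario",
    "make_toeplitz_scenario",
    "snr_beta",
    "snr_c",
]


@dataclass
class QtlScenario:
    n: int = 200
    s: int = 30
    p: int = 300
    graph_kind: str = "block-diagonal"   # | 'decomposable' | 'non-decomposable'
    r: float = 0.3                       # off-diagonal of the G-Wishart scale
    target_snr_beta: float = 5.0
    snr_window: float = 0.1              # ±10% acceptance window
    effect_mean: float = 5.0
    effect_sd: float = 1.0
    n_blocks: int = 3                    # block-diagonal structure
    clique_size: int = 10                # decomposable/non-decomposable cliques
    overlap: int = 3
    n_hotspot: int = 2
    n_mixed: int = 2
    seed: int = 0


@dataclass
class ToeplitzScenario:
    scenario_id: int = 1                 # bands (0.5), (0.5,0.4), (0.5,0.4,0.3)
    n: int = 150
    p: int = 30
    s: int = 20
    n_nonzero_coef: int = 120
    coef_low: float = -2.0
    coef_high: float = 2.0
    ar: float = 0.7
    seed: int = 0

    @property
    def bands(self):
        return {1: (0.5,), 2: (0.5, 0.4), 3: (0.5, 0.4, 0.3)}[self.scenario_id]


@dataclass
class QtlData:
    Y: np.ndarray
    X: np.ndarray
    gamma: np.ndarray          # s×p truth
    beta: np.ndarray           # s×p truth
    adjacency: np.ndarray      # s×s truth graph
    C: np.ndarray              # residual covariance actually used
    snr_beta: float
    snr_c: float
    alpha: float
    groups: dict = field(default_factory=dict)


def make_genotype_like_predictors(n: int, p: int, rng, block_size: int = 10,
                                  ar: float = 0.95, maf_range=(0.05, 0.5)):
    """0/1/2 dosage matrix with LD-like block-AR correlation.

    A latent Gaussian with AR(ar) correlation within blocks of loci is
    thresholded at the Hardy-Weinberg quantiles of a per-locus allele
    frequency, so pairwise dosage correlations range from near zero
    (between blocks) to above 0.8 (adjacent loci).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    X = np.zeros((n, p))
    start = 0
    while start < p:
        b = min(block_size, p - start)
        # AR(ar) latent: z_j = ar * z_{j-1} + sqrt(1-ar^2) * eps
        zb = np.zeros((n, b))
        zb[:, 0] = rng.standard_normal(n)
        for j in range(1, b):
            zb[:, j] = ar * zb[:, j - 1] + np.sqrt(1 - ar * ar) * rng.standard_normal(n)
        f = rng.uniform(*maf_range, size=b)
        q0 = stats.norm.ppf((1 - f) ** 2)          # P(dosage 0)
        q1 = stats.norm.ppf((1 - f) ** 2 + 2 * f * (1 - f))
        Xb = np.zeros((n, b))
        Xb[zb > q0] = 1.0
        Xb[zb > q1] = 2.0
        X[:, start:start + b] = Xb
        start += b
    return X


def _construction_cliques(kind: str, s: int, n_blocks: int, clique_size: int,
                          overlap: int):
    """The cliques used to build each graph kind (pattern groups for γ)."""
    if kind == "block-diagonal":
        bounds = np.linspace(0, s, n_blocks + 1).astype(int)
        return [list(range(bounds[b], bounds[b + 1])) for b in range(n_blocks)]
    step = clique_size - overlap
    starts = list(range(0, max(s - overlap, 1), step))
    cliques = [list(range(a, min(a + clique_size, s))) for a in starts]
    cliques = [c for c in cliques if len(c) > 1]
    if kind == "non-decomposable":
        cliques.append(sorted(set(range(s - overlap, s)) | set(range(overlap))))
    return cliques


def make_graph(kind: str, s: int, n_blocks: int = 3, clique_size: int = 10,
               overlap: int = 3) -> np.ndarray:
    """Ground-truth residual graph adjacency.

    block-diagonal: disjoint complete blocks. decomposable: a chain of
    overlapping cliques (chordal). non-decomposable: the same chain closed
    into a ring, which introduces a long chordless cycle.
    """
    adj = np.zeros((s, s), dtype=bool)
    if kind == "block-diagonal":
        bounds = np.linspace(0, s, n_blocks + 1).astype(int)
        for b in range(n_blocks):
            idx = np.arange(bounds[b], bounds[b + 1])
            adj[np.ix_(idx, idx)] = True
    elif kind in ("decomposable", "non-decomposable"):
        step = clique_size - overlap
        if step <= 0:
            raise ValueError("overlap must be smaller than clique_size")
        starts = list(range(0, max(s - overlap, 1), step))
        cliques = [np.arange(a, min(a + clique_size, s)) for a in starts]
        cliques = [c for c in cliques if c.size > 1]
        for c in cliques:
            adj[np.ix_(c, c)] = True
        if kind == "non-decomposable":
            # close the clique chain into a ring: overlap the last clique with
            # the first nodes, creating a chordless cycle at the clique level
            tail = np.arange(s - overlap, s)
            head = np.arange(0, overlap)
            ring = np.concatenate([tail, head])
            adj[np.ix_(ring, ring)] = True
    else:
        raise ValueError(f"unknown graph kind: {kind!r}")
    np.fill_diagonal(adj, False)
    if kind == "non-decomposable" and gr.is_decomposable(adj):
        raise ValueError("constructed graph is unexpectedly chordal; "
                         "increase s or adjust clique_size/overlap")
    return adj


def sample_precision_gwishart(adjacency: np.ndarray, df: float, scale: np.ndarray,
                              rng, ips_tol: float = 1e-8, ips_max_iter: int = 500):
    """Draw a precision matrix from the G-Wishart W_G(df, scale).

    Decomposable graphs: exact, through the transformed hyper inverse-Wishart
    sampler (K = C^{-1} with C ~ HIW_G(df + s − 1, scale) in this package's
    inverse-Wishart convention); the zero pattern matches the graph exactly.
    Non-decomposable graphs: approximate — a full Wishart draw is projected
    onto the graph's zero pattern by iterative proportional scaling over the
    vertices and edges (documented approximation; used for data generation
    only, never for inference).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    adjacency = np.asarray(adjacency, dtype=bool)
    s = adjacency.shape[0]
    scale = np.asarray(scale, dtype=float)
    np.linalg.cholesky(scale)  # raises on non-SPD
    if gr.is_decomposable(adjacency):
        jt = gr.build_junction_tree(adjacency)
        peo = gr.perfect_elimination_order(jt)
        prior = cov.CovPriorParams(nu=df + s - 1, tau=1.0)
        rc = cov.sample_prior(jt, prior, rng, M=scale, peo=peo)
        C = cov.reconstruct_covariance(rc, peo.order)
        K = np.linalg.inv(C)
        K[~adjacency & ~np.eye(s, dtype=bool)] = 0.0  # remove numerical dust
        K = 0.5 * (K + K.T)
        return K
    # non-decomposable: Wishart draw, then IPS projection of its inverse
    full_df = df + s - 1
    W = stats.wishart.rvs(df=full_df, scale=np.linalg.inv(scale), random_state=rng)
    target = np.linalg.inv(W)  # covariance whose vertex/edge margins we match
    K = np.diag(1.0 / np.diag(target))
    cliques = [(i,) for i in range(s)]
    cliques += [(i, j) for i in range(s) for j in range(i + 1, s) if adjacency[i, j]]
    for _ in range(ips_max_iter):
        delta = 0.0
        Sigma = np.linalg.inv(K)
        for c in cliques:
            c = np.asarray(c)
            Scc = Sigma[np.ix_(c, c)]
            Tcc = target[np.ix_(c, c)]
            upd = np.linalg.inv(Tcc) - np.linalg.inv(Scc)
            K[np.ix_(c, c)] += upd
            delta = max(delta, float(np.abs(Scc - Tcc).max()))
            Sigma = np.linalg.inv(K)
        if delta < ips_tol:
            break
    K[~adjacency & ~np.eye(s, dtype=bool)] = 0.0
    return 0.5 * (K + K.T)


def make_gamma_pattern(s: int, p: int, adjacency: np.ndarray, rng,
                       n_hotspot: int = 2, n_mixed: int = 2, cliques=None):
    """Structured truth γ: hotspots (all responses), per-prime, per-residual,
    and cross-component predictors; all other predictors are null.

    For a non-decomposable graph (no junction tree) pass the construction
    ``cliques``; they play the role of primes, and their sequential
    set-differences that of residuals.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    if cliques is not None:
        primes = [sorted(c) for c in cliques]
        residuals = []
        hist = set()
        for c in primes:
            residuals.append(sorted(set(c) - hist) or sorted(c))
            hist |= set(c)
    elif gr.is_decomposable(adjacency):
        jt = gr.build_junction_tree(adjacency)
        primes = [sorted(c) for c in jt.primes]
        residuals = [sorted(c) for c in jt.residuals]
    else:
        raise ValueError("non-decomposable graph: supply the construction cliques")
    n_groups = n_hotspot + len(primes) + len(residuals) + n_mixed
    if n_groups > p:
        raise ValueError("not enough predictors for the association pattern")
    cols = rng.choice(p, size=n_groups, replace=False)
    gamma = np.zeros((s, p), dtype=bool)
    groups = {"hotspot": [], "prime": [], "residual": [], "mixed": []}
    i = 0
    for _ in range(n_hotspot):
        gamma[:, cols[i]] = True
        groups["hotspot"].append(int(cols[i]))
        i += 1
    for pr in primes:
        gamma[pr, cols[i]] = True
        groups["prime"].append(int(cols[i]))
        i += 1
    for res in residuals:
        gamma[res, cols[i]] = True
        groups["residual"].append(int(cols[i]))
        i += 1
    for _ in range(n_mixed):
        # span at least two components: half of one prime plus half of another
        a, b = rng.choice(len(primes), size=2, replace=len(primes) < 2)
        pa, pb = primes[int(a)], primes[int(b)]
        pick = sorted(set(pa[: max(1, len(pa) // 2)]) | set(pb[len(pb) // 2:]))
        gamma[pick, cols[i]] = True
        groups["mixed"].append(int(cols[i]))
        i += 1
    return gamma, groups


def snr_beta(X, beta, gamma, sigma2) -> float:
    """Predictor signal-to-noise: mean over responses of the per-sample
    fitted-mean energy divided by the conditional residual variance."""
    n = X.shape[0]
    s = beta.shape[0]
    total = 0.0
    for k in range(s):
        mu = X @ (beta[k] * gamma[k])
        total += (mu @ mu) / (n - 1) / sigma2[k]
    return float(total / s)


def snr_c(U, rho, sigma2) -> float:
    """Covariance signal-to-noise: energy of the earlier-residual regression
    term, relative to the conditional variances (ordering of ``rho``)."""
    n, s = U.shape
    total = 0.0
    for k in range(s):
        mu = U[:, :k] @ rho[k, :k] if k else np.zeros(n)
        total += (mu @ mu) / (n - 1) / sigma2[k]
    return float(total / s)


def _alpha_grid(lo=1e-4, hi=1e6, per_decade=32):
    n_dec = np.log10(hi / lo)
    return np.logspace(np.log10(lo), np.log10(hi), int(round(n_dec * per_decade)) + 1)


def simulate_qtl_scenario(sc: QtlScenario) -> QtlData:
    """Generate one replicate of a QTL scenario.

    The G-Wishart precision is drawn once at unit scale; the scale α of
    M = αR multiplies the implied covariance, so the α grid is searched until
    the achieved SNR_β lands inside the ±window acceptance band.
    """
    rng = np.random.default_rng(sc.seed)
    X = make_genotype_like_predictors(sc.n, sc.p, rng)
    # analysis-scale predictors: centred, unit-variance dosages (the model is
    # fit on standardised data; the SNR is defined on that scale)
    X = (X - X.mean(axis=0)) / np.clip(X.std(axis=0), 1e-8, None)
    adjacency = make_graph(sc.graph_kind, sc.s, n_blocks=sc.n_blocks,
                           clique_size=sc.clique_size, overlap=sc.overlap)
    cliques = _construction_cliques(sc.graph_kind, sc.s, sc.n_blocks,
                                    sc.clique_size, sc.overlap)
    gamma, groups = make_gamma_pattern(sc.s, sc.p, adjacency, rng,
                                       n_hotspot=sc.n_hotspot, n_mixed=sc.n_mixed,
                                       cliques=cliques)
    beta = np.where(gamma, rng.normal(sc.effect_mean, sc.effect_sd, size=(sc.s, sc.p)), 0.0)
    R = np.full((sc.s, sc.s), sc.r) + (1 - sc.r) * np.eye(sc.s)
    K1 = sample_precision_gwishart(adjacency, df=sc.s + 2, scale=R, rng=rng)
    C1 = np.linalg.inv(K1)
    C1 = 0.5 * (C1 + C1.T)
    rc1 = cov.decompose_covariance(C1, np.arange(sc.s))
    energies = np.array([
        float(np.sum((X @ (beta[k] * gamma[k])) ** 2)) / (sc.n - 1)
        for k in range(sc.s)
    ])
    alpha = None
    for a in _alpha_grid():
        val = float(np.mean(energies / (a * rc1.sigma2)))
        if abs(val - sc.target_snr_beta) <= sc.snr_window * sc.target_snr_beta:
            alpha = a
            break
    if alpha is None:
        raise RuntimeError(
            f"alpha grid exhausted: SNR_beta range "
            f"[{float(np.mean(energies / (1e3 * rc1.sigma2))):.3g}, "
            f"{float(np.mean(energies / (1e-3 * rc1.sigma2))):.3g}] "
            f"never meets target {sc.target_snr_beta} within "
            f"{sc.snr_window:.0%}")
    C = alpha * C1
    E = rng.standard_normal((sc.n, sc.s)) @ np.linalg.cholesky(C).T
    Y = X @ beta.T + E
    sig = alpha * rc1.sigma2
    achieved_beta = snr_beta(X, beta, gamma, sig)
    achieved_c = snr_c(E, rc1.rho, sig)
    return QtlData(Y=Y, X=X, gamma=gamma, beta=beta, adjacency=adjacency, C=C,
                   snr_beta=achieved_beta, snr_c=achieved_c, alpha=float(alpha),
                   groups=groups)


def make_toeplitz_scenario(sc: ToeplitzScenario):
    """Generate one replicate of a banded-Toeplitz-precision benchmark.

    Returns (Y, X, B, precision) with B the s×p coefficient truth (exactly
    ``n_nonzero_coef`` nonzero cells) and ``precision`` the banded Toeplitz
    inverse error covariance.
    """
    rng = np.random.default_rng(sc.seed)
    V = sc.ar ** np.abs(np.subtract.outer(np.arange(sc.p), np.arange(sc.p)))
    X = rng.standard_normal((sc.n, sc.p)) @ np.linalg.cholesky(V).T
    ncells = sc.s * sc.p
    cells = rng.choice(ncells, size=sc.n_nonzero_coef, replace=False)
    B = np.zeros(ncells)
    B[cells] = rng.uniform(sc.coef_low, sc.coef_high, size=sc.n_nonzero_coef)
    B = B.reshape(sc.s, sc.p)
    prec = np.eye(sc.s)
    for d, v in enumerate(sc.bands, start=1):
        prec += v * (np.eye(sc.s, k=d) + np.eye(sc.s, k=-d))
    np.linalg.cholesky(prec)  # all three band sets are SPD
    T = np.linalg.inv(prec)
    T = 0.5 * (T + T.T)
    Y = X @ B.T + rng.standard_normal((sc.n, sc.s)) @ np.linalg.cholesky(T).T
    return Y, X, B, prec
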