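# Methods

## Model

`sparsesur` fits a seemingly-unrelated-regressions (SUR) model for an n×s
response matrix Y and a shared n×p predictor matrix X:

    y_k = X_γk β_γk + u_k,          k = 1..s,
    u_i· ~ N(0, C)                  independently over samples i,

with *cell sparsity*: a binary indicator γ_kj selects predictor j into the
regression of response k independently of the other responses. Coefficients
follow a spike-and-slab prior, β_kj | γ_kj ~ γ_kj·N(0, w) + (1−γ_kj)·δ₀ with
w ~ IGa(a_w, b_w), and inclusions follow the hotspot prior
γ_kj ~ Bernoulli(o_k·π_j) under the constraint o_k π_j ≤ 1: o_k ~ Beta(a_o, b_o)
is the sparsity level of response k and π_j ~ Ga(a_π, b_π) the propensity of
predictor j to associate with many responses. Setting π ≡ 1 gives the
beta-binomial variant.

### Covariance reparametrisation

The residual covariance C is never sampled directly. Given a node ordering,
C is encoded by the sequential conditional variances and regressions

    σ²_k = c_k − 𝐜_kᵀ C_(k−1)^{-1} 𝐜_k,     ρ_k = C_(k−1)^{-1} 𝐜_k,

which factorise the likelihood into s independent Gaussian regressions of
y_k on (X_γk, earlier residuals). Priors are derived in this transformed
space:

* **dense** — C ~ IW(ν, τI) transforms to independent
  σ²_k ~ IGa((ν−s+k)/2, τ/2), ρ_k | σ²_k ~ N(0, (σ²_k/τ)I);
* **sparse** — a decomposable graph G restricts the residual precision; with
  C ~ HIW_G(ν, τI) and nodes in a perfect elimination order of G, ρ_k is
  supported on the earlier-ordered neighbours L(k) of k and
  σ²_k ~ IGa((ν − s + |L(k)| + 1)/2, τ/2). The structural zeros in ρ realise
  the precision zeros exactly — no completion step is ever needed. (The
  shape can be read as (ν − s + t + |S_q|)/2 with t the within-residual index
  and S_q the separator; |L(k)| + 1 = t + |S_q| under the clique-sequence
  ordering.)

The ordering used is: nodes of the first prime component ascending, then the
residual of each subsequent prime in the perfect sequence; in this ordering
the *earlier* neighbours of every node form a clique (the reverse of the
ordering is the textbook elimination direction). All totals that matter —
the likelihood and the collapsed marginals — are invariant to the particular
valid ordering, which the tests check.

τ (the prior scale of C) gets a Ga(a_τ, b_τ) hyperprior and a log-scale
random-walk Metropolis update; the graph edge probability η gets a
conjugate Beta(a_η, b_η) prior with a Gibbs update from
Beta(a_η + |J|, b_η + s(s−1)/2 − |J|).

### Graph prior and state

The graph prior is proportional to a binomial on the edge count,
p(J | η) ∝ C(K, |J|) η^|J| (1−η)^{K−|J|} with K = s(s−1)/2. With
a_η = b_η = 1 the implied marginal prior on the edge count is uniform, so
there is no combinatorial push toward dense or empty graphs. The sampler's
state is the decomposable graph, held as its canonical junction tree
(deterministic greedy perfect sequence over the maximal cliques, built from
maximum-cardinality search with lowest-index tie-breaks); disconnected
graphs are junction forests joined by empty separators.

## Sampler

One sweep performs, in order:

1. **Joint {J*, σ²*, ρ*} update** (sparse mode). A graph move is proposed
   (see below) and accepted with a ratio containing only the
   (σ², ρ)-collapsed likelihood of the current residuals, the edge-count
   prior and the proposal ratio — proposing (σ², ρ) from their exact full
   conditionals makes their densities cancel (implicit marginalisation). A
   Gibbs refresh of (σ², ρ) from the full conditionals under the resulting
   graph follows, so the dense mode is the strict special case "no graph
   move, pure Gibbs draw". Several graph sub-moves run per sweep
   (`graph_moves_per_sweep`, default 5) because one structural move per
   full sweep mixes the graph far more slowly than the regression block.
2. **Joint {γ*_k, β*_γk} updates**, one per response. A local add/delete/swap
   move (probabilities 0.4/0.4/0.2) proposes γ*_k; β* is drawn from its
   exact conditional, whose working response folds in the feedback from
   later-ordered same-prime responses; the
   acceptance uses the β-collapsed marginal, the hotspot prior and the move
   ratio. Residual column u_k is refreshed only on acceptance.
3. **Hotspot updates**: o_k by an independence proposal from
   Beta(a_o + |γ_k|, b_o + p − |γ_k|) (exactly conjugate in the
   beta-binomial variant), π_j by adaptive log-scale random walks; proposals
   violating o_k π_j ≤ 1 are rejected outright.
4. **w** by its conjugate inverse-gamma draw, **τ** by Metropolis,
   **η** by Gibbs.

σ² and ρ are nuisance state: only current values are kept, never traced.
mPIP/mEPIP are running means of γ and the graph adjacency over post-burn-in
sweeps of the cold chain (model averaging over decomposable graphs — the
averaged network may be non-decomposable).

### Graph proposals

The proposal mixes (80/10/10):

* a **single-edge toggle**, uniform over all node pairs (symmetric;
  a non-chordal result is an automatic rejection);
* a **merge**: pick a junction-tree edge (P_a, S, P_b) and complete
  P_a ∪ P_b, connecting the subsets P_a\S and P_b\S in one move (valid only
  when no edge between them already exists, which makes the reverse split
  unique);
* a **split**: pick a prime P, assign its nodes independently to (A, B, S),
  and delete the A×B edges (valid when A, B are nonempty, every deleted
  edge lives only in P, the result is chordal, and the reverse merge exists
  in the canonical junction tree of the result).

The forward and reverse probabilities are computed exactly by summing every
mechanism that maps one graph to the other (a one-edge merge is also a
toggle, two primes can license the same split, and so on). A prior-only
chain with this kernel reproduces the brute-force enumerated edge-count
prior on five nodes — the strongest end-to-end check of the ratios.

### Tempered ensemble

Selection moves are embedded in a small evolutionary-stochastic-search-style
ensemble: `n_chains` copies run at temperatures 1 = T₁ < T₂ < …, where the
tempered target p(Y|θ)^{1/T} p(θ) is implemented exactly by handing chain i
the scaled data (X, Y)/√T_i with effective sample size n/T_i. Whole states
are exchanged between adjacent temperatures with the standard
parallel-tempering acceptance; during burn-in the temperature gap adapts
toward a 0.25 exchange rate (Robbins–Monro on log(T−1), frozen afterwards,
as are all proposal-scale adaptations). Crossover moves between chains are
not implemented — the move mixture is an open design choice here, and
exchanges alone already give the cold chain the intended mobility. Only the
cold chain contributes to posterior summaries.

## Default hyperparameters

| parameter | default | rationale |
|---|---|---|
| a_o, b_o | 2, p−2 | prior mean model size ≈ 2 per response, variance ≈ 2 — strong sparsity for QTL panels |
| a_π, b_π | 1/2, 1/2 | E(π_j) = 1: the hotspot propensity is a tilt, not a scale |
| a_w, b_w | 0.1, 0.1 | diffuse slab variance on standardised data |
| a_τ, b_τ | 0.1, 0.1 | diffuse covariance scale on standardised data |
| a_η, b_η | 1, 1 | uniform edge probability; with the binomial-coefficient prior, uniform edge count |
| ν | s + 2 | smallest integer-offset choice exceeding s − 1 with a finite prior mean of C; configurable |
| iterations / burn-in | 10000 / 20% | a 20% burn-in fraction, the common operating convention for samplers of this family |

Responses and predictors are standardised by default (the model carries no
intercept); responses can optionally be inverse rank-normal transformed
(Blom offset 3/8, average ranks on ties) at the I/O layer.

## Synthetic designs

`simulate.QtlScenario` (defaults n = 200, s = 30, p = 300) emulates an
mQTL-style study: LD-structured 0/1/2 dosages (block-AR(0.95) latent
Gaussian thresholded at Hardy–Weinberg quantiles of a per-locus allele
frequency in [0.05, 0.5], then centred and scaled — pairwise correlations
run from ~0 to above 0.8); a true residual graph that is block-diagonal,
an overlapping-clique chordal chain, or that chain closed into a
non-chordal ring; a G-Wishart precision W_G(s+2, αR) on that graph with R
the equicorrelation matrix at level r; association patterns with hotspot,
per-prime, per-residual and cross-component predictors; N(5, 1) effects on
the support; matrix-normal residuals. The scale α is searched on a log grid
(32 points/decade over [1e−4, 1e6]) until the predictor signal-to-noise

    SNR_β = (1/s) Σ_k (n−1)^{-1} Σ_i (x_{i,γk} β_γk)² / σ²_k

falls within ±10% of its target; SNR_C (the analogous energy of the
residual-regression term) is reported alongside. Decomposable G-Wishart
draws are exact (through the transformed hyper-inverse-Wishart sampler,
using K ~ W_G(δ, M) ⟺ K^{-1} ~ HIW_G(δ + s − 1, M) in this package's
inverse-Wishart convention); non-decomposable draws project a full Wishart
draw onto the zero pattern by iterative proportional scaling over vertices
and edges — an approximation used for data generation only, never for
inference.

`simulate.ToeplitzScenario` generates the banded-precision benchmark:
n = 150, p = 30, s = 20, predictors N(0, V) with V_jj' = 0.7^|j−j'|, exactly
120 of the 600 coefficient cells Uniform(−2, 2), and an inverse error
covariance that is Toeplitz with unit diagonal and bands (0.5), (0.5, 0.4)
or (0.5, 0.4, 0.3) — 19/37/54 nonzero upper-triangle entries respectively.

What the generators do **not** emulate: genotype calling artefacts, missing
data, population structure, non-Gaussian phenotype tails (real responses are
rank-normalised away from these), and real LD beyond a stationary block-AR
profile. Passing the simulation suites therefore demonstrates correctness of
the model and sampler under the model's own assumptions, not robustness to
everything a cohort can throw at it.

## Numerical choices

* Schur complements and conditional draws go through Cholesky
  factorisations (LAPACK `dpotrf`/`dtrtrs`); on failure a jitter of
  1e−10·trace/dim is added once before giving up.
* The collapsed graph-likelihood is cached per node and only the nodes whose
  earlier-neighbour set changed are recomputed after a graph proposal (each
  per-node term depends on L(k) as a set, so the cache is ordering-proof).
* Adaptive scales (τ, π_j) target 0.44 acceptance; the exchange temperature
  targets 0.25; all adaptation freezes at the end of burn-in.
* Ties in all deterministic constructions (MCS, clique ordering, residual
  ordering) break toward the lowest node index, so a graph has exactly one
  canonical junction tree and runs are bitwise reproducible from the seed.
* Degenerate selections (collinear chosen columns) stay invertible through
  the w^{-1}I ridge in the β-conditional precision.

## Problem sizes used in the shipped checks

Production analyses of this kind run hundreds of thousands of sweeps at s in
the tens to hundreds; the packaged acceptance study uses a reduced design
chosen to preserve the qualitative regime (block size 10 and n = 200 are
kept, SNR_β = 5): s = 20 responses (two blocks of 10 for the
block-diagonal case; cliques of 10 overlapping by 3 for the chordal chain
and its non-chordal ring closure), p = 60 predictors, 8000 iterations with
1600 burn-in, a single chain, and three replicates per scenario. Edge
recovery at these sizes is dominated by the same two forces as at full
scale: per-edge evidence from the n samples, and the decomposability
fill-in that large cliques impose on their weakest edges. A caveat worth
stating plainly: a noticeable fraction of the true edges drawn from a
G-Wishart precision with an equicorrelation scale carry near-zero partial
correlations, and the exact posterior (verified against exhaustive
enumeration on small graphs) excludes them at n = 200; the edge true
positive rates this package reports are therefore its honest posterior
behaviour under these generative conditions, not a tuned reproduction of
any particular published figure.

## Known limitations

* Graph inference is restricted to decomposable graphs; non-decomposable
  truths are recovered only through model averaging, with the expected
  over-inclusion around chordless cycles.
* One shared predictor matrix X for all responses (the general formulation
  allows response-specific X_k).
* The per-response conditional updates are independent given (U, σ², ρ) and
  could run concurrently; this build executes them serially (the reference
  semantics), and promises per-mode determinism only.
* G-Wishart draws on non-decomposable graphs are approximate (IPS
  projection), which only affects synthetic data generation.
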