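"""Decomposable (chordal) graph state for sparse residual covariance selection.

The residual graph ``G`` over the ``s`` responses is restricted to be
decomposable and is manipulated through its junction tree: the ordered prime
components (maximal cliques) ``P_1..P_Q``, the separators ``S_q = P_q ∩ H_q``
with history ``H_q = P_1 ∪ .. ∪ P_{q-1}``, and the residuals ``R_q = P_q \\ S_q``.
A perfect elimination order of the nodes (all of ``P_1`` first, then the
residuals in prime order) drives the covariance reparametrisation downstream.

Graph moves are a mixture of single-edge toggles and multi-edge merge/split
moves on adjacent primes of the canonical junction tree; the exact proposal
probability of a transition is computed by summing over every mechanism that
produces it, so the moves are usable inside Metropolis-Hastings.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, log

import numpy as np

__all__ = [
    "DecomposableGraph",
    "JunctionTree",
    "PerfectEliminationOrder",
    "NotDecomposableError",
    "build_junction_tree",
    "perfect_elimination_order",
    "propose_graph_move",
    "proposal_log_prob",
    "log_graph_prior",
    "gibbs_update_eta",
    "sample_graph_prior_chain",
    "is_decomposable",
]


class NotDecomposableError(ValueError):
    """Raised when a graph fails the chordality test.

    Carries ``cycle``, a chordless cycle of length >= 4 witnessing the failure
    (1-based node labels in the message, 0-based in the attribute).
    """

    def __init__(self, cycle):
        self.cycle = list(cycle)
        labels = [c + 1 for c in self.cycle]
        super().__init__(
            f"graph is not decomposable: chordless cycle {labels} (1-based nodes)"
        )


@dataclass(frozen=True)
class DecomposableGraph:
    """Symmetric boolean adjacency with empty diagonal, known to be chordal."""

    adjacency: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if a.diagonal().any():
            raise ValueError("adjacency diagonal must be empty")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        object.__setattr__(self, "adjacency", a)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def _adj_bits(adjacency: np.ndarray) -> list[int]:
    """Adjacency rows as python int bitmasks (fast set algebra at small s)."""
    s = adjacency.shape[0]
    return [int.from_bytes(np.packbits(adjacency[i], bitorder="little").tobytes(), "little") for i in range(s)]


def _mcs(bits: list[int], s: int):
    """Maximum cardinality search with lowest-index tie-breaking.

    Returns (visit_order, chordal, witness) where witness is ``(v, u, w)``
    such that w, u are earlier-visited neighbours of v that are not adjacent
    (only set when chordal is False).
    """
    weights = [0] * s
    visited = 0
    order = []
    earlier = [0] * s  # earlier-visited neighbours of each node, as bitmask
    for _ in range(s):
        best, best_w = -1, -1
        for v in range(s):
            if not (visited >> v) & 1 and weights[v] > best_w:
                best, best_w = v, weights[v]
        v = best
        m = bits[v] & visited
        earlier[v] = m
        order.append(v)
        visited |= 1 << v
        nb = bits[v] & ~visited
        while nb:
            u = (nb & -nb).bit_length() - 1
            weights[u] += 1
            nb &= nb - 1
    # chordality: for each v, earlier neighbours minus the latest one must be
    # contained in the closed neighbourhood of that latest one
    pos = {v: i for i, v in enumerate(order)}
    for v in order:
        m = earlier[v]
        if m == 0 or m & (m - 1) == 0:
            continue
        u = max((x for x in _iter_bits(m)), key=lambda x: pos[x])
        rest = m & ~(1 << u)
        bad = rest & ~(bits[u] | (1 << u))
        if bad:
            w = (bad & -bad).bit_length() - 1
            return order, False, (v, u, w)
    return order, True, None


def _iter_bits(mask: int):
    while mask:
        yield (mask & -mask).bit_length() - 1
        mask &= mask - 1


def _chordless_cycle(adjacency: np.ndarray, witness) -> list[int]:
    """Expand an MCS failure witness (v, u, w) into a chordless cycle.

    u and w are non-adjacent neighbours of v; a shortest u-w path avoiding
    N[v] \\ {u, w} closes a cycle through v with no chord.
    """
    v, u, w = witness
    s = adjacency.shape[0]
    blocked = set(np.flatnonzero(adjacency[v])) | {v}
    blocked -= {u, w}
    # BFS from u to w in the graph minus blocked
    prev = {u: None}
    queue = [u]
    while queue:
        x = queue.pop(0)
        if x == w:
            break
        for y in np.flatnonzero(adjacency[x]):
            y = int(y)
            if y not in prev and y not in blocked:
                prev[y] = x
                queue.append(y)
    path = []
    x = w
    while x is not None:
        path.append(x)
        x = prev[x]
    return [v] + path[::-1]  # v, u, ..., w


def is_decomposable(adjacency: np.ndarray) -> bool:
    a = np.asarray(adjacency, dtype=bool)
    _, ok, _ = _mcs(_adj_bits(a), a.shape[0])
    return ok


@dataclass
class JunctionTree:
    """Junction tree (forest joined by empty separators) of a chordal graph."""

    graph: DecomposableGraph
    primes: list[frozenset]          # P_1..P_Q in a perfect sequence
    separators: list[frozenset]      # S_1 = {} by convention, then S_2..S_Q
    residuals: list[frozenset]       # R_1 = P_1, then R_2..R_Q
    histories: list[frozenset]       # H_1 = {}, H_q = P_1 ∪ .. ∪ P_{q-1}
    tree_edges: list[int]            # parent prime index per q (-1 for q=0)

    @property
    def n_primes(self) -> int:
        return len(self.primes)

    @property
    def n_graph_edges(self) -> int:
        return self.graph.n_edges

    def validate(self) -> None:
        """Check running intersection, residual identities and edge count."""
        union = set()
        for q, p in enumerate(self.primes):
            h = self.histories[q]
            sep = self.separators[q]
            assert h == frozenset(union), "history mismatch"
            assert sep == p & h, "separator is not P_q ∩ H_q"
            assert self.residuals[q] == p - sep, "residual is not P_q \\ S_q"
            if q > 0:
                parent = self.tree_edges[q]
                assert 0 <= parent < q, "parent must precede child"
                assert sep <= self.primes[parent], "running intersection fails"
            union |= p
        adj = np.zeros_like(self.graph.adjacency)
        for p in self.primes:
            idx = sorted(p)
            for i in idx:
                for j in idx:
                    if i != j:
                        adj[i, j] = True
        assert np.array_equal(adj, self.graph.adjacency), "induced graph mismatch"


def _maximal_cliques_chordal(adjacency: np.ndarray) -> list[frozenset]:
    """Maximal cliques of a chordal graph from a perfect elimination order."""
    bits = _adj_bits(adjacency)
    s = adjacency.shape[0]
    order, ok, witness = _mcs(bits, s)
    if not ok:
        raise NotDecomposableError(_chordless_cycle(adjacency, witness))
    pos = [0] * s
    for i, v in enumerate(order):
        pos[v] = i
    # elimination order = reverse MCS visit order; candidate clique of v is
    # v plus its neighbours visited before v in MCS order
    cands = []
    for v in order:
        m = bits[v] & _mask_of([u for u in range(s) if pos[u] < pos[v]])
        cands.append((1 << v) | m)
    # drop non-maximal candidates (subset of another)
    maximal = []
    for i, c in enumerate(cands):
        if not any(c != d and c & d == c for d in cands):
            if c not in maximal:
                maximal.append(c)
    return [frozenset(_iter_bits(c)) for c in maximal]


def _mask_of(nodes) -> int:
    m = 0
    for v in nodes:
        m |= 1 << v
    return m


def build_junction_tree(graph) -> JunctionTree:
    """Junction tree of a decomposable graph.

    Primes are ordered greedily by maximal intersection with the running
    history (deterministic, lowest-index tie-break), which yields a perfect
    sequence satisfying the running intersection property. Disconnected
    graphs produce a forest whose components are joined by empty separators.

    Raises
    ------
    NotDecomposableError
        If the input graph is not chordal; the error names a chordless cycle.
    """
    if not isinstance(graph, DecomposableGraph):
        graph = DecomposableGraph(np.asarray(graph, dtype=bool))
    cliques = _maximal_cliques_chordal(graph.adjacency)
    # deterministic base order: sort by (min node, tuple)
    cliques = sorted(cliques, key=lambda c: tuple(sorted(c)))
    Q = len(cliques)
    used = [False] * Q
    primes, separators, residuals, histories, parents = [], [], [], [], []
    history = set()
    # start from the clique containing the lowest node
    for step in range(Q):
        best, best_score = -1, -1
        for i in range(Q):
            if used[i]:
                continue
            score = len(cliques[i] & history) if step else -len(cliques[i]) * 0
            if step == 0:
                # first: clique with the smallest minimum node
                if best == -1:
                    best = i
                continue
            if score > best_score:
                best, best_score = i, score
        i = best
        used[i] = True
        p = cliques[i]
        sep = frozenset(p & history)
        parent = -1
        if step > 0:
            for q, pq in enumerate(primes):
                if sep <= pq:
                    parent = q
                    break
        primes.append(p)
        separators.append(sep)
        residuals.append(p - sep)
        histories.append(frozenset(history))
        parents.append(parent)
        history |= p
    jt = JunctionTree(graph, primes, separators, residuals, histories, parents)
    return jt


@dataclass(frozen=True)
class PerfectEliminationOrder:
    """Node ordering ``xi`` with per-node prime index q(k) and residual index t."""

    order: np.ndarray      # order[i] = node at position i (0-based)
    position: np.ndarray   # position[k] = xi(k) (0-based)
    prime_index: np.ndarray  # q(k), 0-based prime/residual index
    residual_index: np.ndarray  # t(k) = xi(k) - |H_q|, 1-based as in the density


def perfect_elimination_order(jt: JunctionTree) -> PerfectEliminationOrder:
    """Perfect elimination order: P_1 ascending, then residuals in prime order.

    In this ordering the earlier-ordered neighbours of every node form a
    clique (its reverse is the textbook elimination direction); that is the
    property the sequential covariance decomposition relies on. Node order
    within a residual is ascending node index (the transformed density does
    not depend on this choice).
    """
    s = jt.graph.n_nodes
    order = []
    q_of = np.zeros(s, dtype=int)
    t_of = np.zeros(s, dtype=int)
    for q in range(jt.n_primes):
        block = sorted(jt.residuals[q])
        h = len(order)
        for t, k in enumerate(block, start=1):
            q_of[k] = q
            t_of[k] = t
            order.append(k)
    order = np.asarray(order, dtype=int)
    position = np.empty(s, dtype=int)
    position[order] = np.arange(s)
    return PerfectEliminationOrder(order, position, q_of, t_of)


def earlier_neighbour_sets(adjacency: np.ndarray, peo: PerfectEliminationOrder):
    """L(k): earlier-ordered neighbours of each node (== earlier same-prime nodes)."""
    s = adjacency.shape[0]
    pos = peo.position
    out = []
    for k in range(s):
        nb = np.flatnonzero(adjacency[k])
        out.append(np.asarray(sorted((int(l) for l in nb if pos[l] < pos[k]),
                                     key=lambda l: pos[l]), dtype=int))
    return out


# ---------------------------------------------------------------------------
# Edge-count prior and eta update
# ---------------------------------------------------------------------------

def log_graph_prior(jt_or_n_edges, eta: float, s: int | None = None) -> float:
    """log p(J | eta) = log C(K, |J|) + |J| log eta + (K-|J|) log(1-eta).

    ``K = s(s-1)/2``. Accepts a JunctionTree or an explicit edge count with s.
    """
    if not 0.0 < eta < 1.0:
        raise ValueError("eta must lie in (0, 1)")
    if isinstance(jt_or_n_edges, JunctionTree):
        ne = jt_or_n_edges.n_graph_edges
        s = jt_or_n_edges.graph.n_nodes
    else:
        ne = int(jt_or_n_edges)
        if s is None:
            raise ValueError("s required with an explicit edge count")
    K = s * (s - 1) // 2
    return log(comb(K, ne)) + ne * log(eta) + (K - ne) * log(1.0 - eta)


def gibbs_update_eta(jt: JunctionTree, a_eta: float, b_eta: float, rng) -> float:
    """Conjugate draw eta ~ Beta(a_eta + |J|, b_eta + s(s-1)/2 - |J|)."""
    s = jt.graph.n_nodes
    K = s * (s - 1) // 2
    ne = jt.n_graph_edges
    return float(rng.beta(a_eta + ne, b_eta + K - ne))


# ---------------------------------------------------------------------------
# Graph proposals
# ---------------------------------------------------------------------------

P_SINGLE = 0.8  # probability of the single-edge toggle mechanism


def _merge_added_edges(adjacency, pa: frozenset, pb: frozenset):
    """Edge set added by completing pa ∪ pb; None if the merge is invalid."""
    sep = pa & pb
    a, b = sorted(pa - sep), sorted(pb - sep)
    added = []
    for x in a:
        for y in b:
            if adjacency[x, y]:
                return None  # an A-B edge already exists: not exactly reversible
            added.append((min(x, y), max(x, y)))
    return added


def _apply_edges(adjacency, edges, value: bool):
    new = adjacency.copy()
    for x, y in edges:
        new[x, y] = new[y, x] = value
    return new


def _split_partition_of(prime: frozenset, removed: frozenset):
    """Recover the unique (A, B) with A x B == removed within ``prime``.

    ``removed`` is a frozenset of (min,max) pairs; returns None if the pairs
    are not a complete bipartite A x B with A, B ⊆ prime.
    """
    nodes = sorted({v for e in removed for v in e})
    if not nodes or not set(nodes) <= prime:
        return None
    # bipartition: two nodes are on the same side iff they are NOT paired
    a_side = {nodes[0]}
    b_side = set()
    for v in nodes[1:]:
        if (min(v, nodes[0]), max(v, nodes[0])) in removed:
            b_side.add(v)
        else:
            a_side.add(v)
    pairs = {(min(x, y), max(x, y)) for x in a_side for y in b_side}
    if pairs != removed:
        return None
    return frozenset(a_side), frozenset(b_side)


def _split_is_valid(adjacency, jt: JunctionTree, prime: frozenset,
                    a_set: frozenset, b_set: frozenset):
    """Check a (prime, A, B) split: removable edges, chordal result, reversible."""
    if not a_set or not b_set:
        return None
    removed = [(min(x, y), max(x, y)) for x in a_set for y in b_set]
    # every removed edge must live only in this prime
    for p in jt.primes:
        if p != prime and p & a_set and p & b_set:
            return None
    new_adj = _apply_edges(adjacency, removed, False)
    if not is_decomposable(new_adj):
        return None
    # reverse merge must exist: A∪S and B∪S adjacent primes of the new JT
    sep = prime - a_set - b_set
    pa, pb = a_set | sep, b_set | sep
    new_jt = build_junction_tree(new_adj)
    prime_ix = {p: q for q, p in enumerate(new_jt.primes)}
    if pa not in prime_ix or pb not in prime_ix:
        return None
    return new_adj, new_jt


def proposal_log_prob(jt_from: JunctionTree, adj_to: np.ndarray) -> float:
    """log q(G_to | G_from) summed over all proposal mechanisms.

    Returns -inf when no mechanism can propose the transition.
    """
    adj_from = jt_from.graph.adjacency
    s = adj_from.shape[0]
    K = s * (s - 1) // 2
    diff = np.triu(adj_from ^ adj_to)
    ndiff = int(diff.sum())
    prob = 0.0
    if ndiff == 0:
        return -np.inf
    if ndiff == 1:
        prob += P_SINGLE / K
    changed = frozenset((int(i), int(j)) for i, j in zip(*np.nonzero(diff)))
    adding = bool(adj_to[next(iter(changed))])
    n_tree_edges = jt_from.n_primes - 1
    if adding and n_tree_edges > 0:
        # merge mechanisms: tree edges whose completion equals the change set
        hits = 0
        for q in range(1, jt_from.n_primes):
            parent = jt_from.tree_edges[q]
            added = _merge_added_edges(adj_from, jt_from.primes[parent], jt_from.primes[q])
            if added is not None and frozenset(added) == changed:
                hits += 1
        if hits:
            prob += (1.0 - P_SINGLE) * 0.5 * hits / n_tree_edges
    elif not adding:
        # split mechanisms: primes containing all changed endpoints
        Q = jt_from.n_primes
        for prime in jt_from.primes:
            part = _split_partition_of(prime, changed)
            if part is None:
                continue
            a_set, b_set = part
            res = _split_is_valid(adj_from, jt_from, prime, a_set, b_set)
            if res is None:
                continue
            if not np.array_equal(res[0], adj_to):
                continue
            prob += (1.0 - P_SINGLE) * 0.5 * 2.0 / (3 ** len(prime)) / Q
    return log(prob) if prob > 0 else -np.inf


def propose_graph_move(jt: JunctionTree, rng):
    """Propose a junction tree differing by connecting/disconnecting node subsets.

    Returns ``(new_jt, log_proposal_ratio)`` with
    ``log_proposal_ratio = log q(J | J*) - log q(J* | J)``, or ``None`` when
    the sampled mechanism produced an invalid (or identity) move, which the
    caller treats as a rejection.
    """
    adj = jt.graph.adjacency
    s = adj.shape[0]
    u = rng.random()
    if u < P_SINGLE:
        i, j = _random_pair(s, rng)
        new_adj = adj.copy()
        new_adj[i, j] = new_adj[j, i] = not adj[i, j]
        if not is_decomposable(new_adj):
            return None
        new_jt = build_junction_tree(new_adj)
    elif u < P_SINGLE + (1 - P_SINGLE) * 0.5:
        # merge two adjacent primes
        if jt.n_primes < 2:
            return None
        q = 1 + int(rng.integers(jt.n_primes - 1))
        parent = jt.tree_edges[q]
        added = _merge_added_edges(adj, jt.primes[parent], jt.primes[q])
        if not added:
            return None
        new_adj = _apply_edges(adj, added, True)
        if not is_decomposable(new_adj):  # pragma: no cover - merge keeps chordality
            return None
        new_jt = build_junction_tree(new_adj)
    else:
        # split a prime into (A, B, S), removing the A x B edges
        q = int(rng.integers(jt.n_primes))
        prime = jt.primes[q]
        labels = rng.integers(3, size=len(prime))
        nodes = sorted(prime)
        a_set = frozenset(v for v, lab in zip(nodes, labels) if lab == 0)
        b_set = frozenset(v for v, lab in zip(nodes, labels) if lab == 1)
        res = _split_is_valid(adj, jt, prime, a_set, b_set)
        if res is None:
            return None
        new_adj, new_jt = res[0], res[1]
    log_fwd = proposal_log_prob(jt, new_adj)
    log_rev = proposal_log_prob(new_jt, adj)
    if not np.isfinite(log_rev):
        return None
    return new_jt, log_rev - log_fwd


def _random_pair(s: int, rng):
    i = int(rng.integers(s))
    j = int(rng.integers(s - 1))
    if j >= i:
        j += 1
    return min(i, j), max(i, j)


def sample_graph_prior_chain(s: int, eta: float, n_steps: int, rng,
                             record_every: int = 1):
    """Prior-only Metropolis-Hastings chain over decomposable graphs.

    Targets p(G) ∝ C(K, |J|) eta^|J| (1-eta)^(K-|J|) restricted to chordal
    graphs, starting from the empty graph. Returns the visited edge counts
    (one per recorded step); used for sampler calibration.
    """
    jt = build_junction_tree(np.zeros((s, s), dtype=bool))
    counts = []
    lp = log_graph_prior(jt, eta)
    for step in range(n_steps):
        move = propose_graph_move(jt, rng)
        if move is not None:
            new_jt, log_ratio = move
            lp_new = log_graph_prior(new_jt, eta)
            if log(rng.random()) < lp_new - lp + log_ratio:
                jt, lp = new_jt, lp_new
        if step % record_every == 0:
            counts.append(jt.n_graph_edges)
    return np.asarray(counts, dtype=int), jt
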