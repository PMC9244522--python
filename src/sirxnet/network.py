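"""Adaptive contact-network state, random-graph generation and motif counting.

Nodes carry one of four epidemiological states — susceptible (S), infected
(I), recovered (R) and quarantined (X) — on a simple undirected graph whose
total number of links is conserved by the dynamics.  The module keeps exact
incremental caches of the S–I and S–S link sets so that the event-driven
simulator can select links uniformly in O(1), and provides an exact motif
counter for the node, pair and centred-triple observables
[S], [I], [R], [X], [SI], [SS], [SSI], [ISI] that drive the moment
hierarchy.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "S",
    "I",
    "R",
    "X",
    "STATE_LABELS",
    "IndexedSet",
    "NetworkConfig",
    "NetworkState",
    "MotifCounts",
    "generate_er_graph",
    "initialize_states",
    "count_motifs",
    "write_edge_list",
    "write_node_states",
]

# Node-state codes.  Kept as plain ints for speed in the event loop.
S, I, R, X = 0, 1, 2, 3
STATE_LABELS = "SIRX"
_LABEL_TO_CODE = {c: k for k, c in enumerate(STATE_LABELS)}


class IndexedSet:
    """A set supporting O(1) add, discard and uniform random sampling.

    Backed by a dense list plus a position index (swap-with-last on
    removal).  Iteration order is arbitrary but deterministic for a given
    operation history, which keeps seeded simulations reproducible.
    """

    __slots__ = ("_items", "_pos")

    def __init__(self, items=()):
        self._items = []
        self._pos = {}
        for x in items:
            self.add(x)

    def add(self, x) -> None:
        if x not in self._pos:
            self._pos[x] = len(self._items)
            self._items.append(x)

    def discard(self, x) -> None:
        k = self._pos.pop(x, None)
        if k is None:
            return
        last = self._items.pop()
        if k < len(self._items):
            self._items[k] = last
            self._pos[last] = k

    def sample(self, rng: np.random.Generator):
        """Uniformly random member; raises IndexError when empty."""
        if not self._items:
            raise IndexError("sample from empty IndexedSet")
        return self._items[int(rng.integers(len(self._items)))]

    def __len__(self) -> int:
        return len(self._items)

    def __contains__(self, x) -> bool:
        return x in self._pos

    def __iter__(self):
        return iter(self._items)

    def as_set(self) -> set:
        return set(self._items)


@dataclass(frozen=True)
class NetworkConfig:
    """Specification of an Erdős–Rényi contact-network ensemble.

    Parameters
    ----------
    n_nodes : int
        Population size N (≥ 2).
    mean_degree : float
        Target mean degree μ; the edge probability is p = μ/(N−1), so the
        expected number of links is K = Nμ/2.
    seed : int
        RNG seed; graph generation is deterministic given the seed.
    """

    n_nodes: int
    mean_degree: float
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be at least 2")
        if not 0 <= self.mean_degree <= self.n_nodes - 1:
            raise ValueError(
                f"mean_degree must lie in [0, n_nodes-1]={self.n_nodes - 1}, "
                f"got {self.mean_degree}"
            )


@dataclass(frozen=True)
class MotifCounts:
    """Exact node, link and centred-triple counts of a network snapshot.

    ``si``/``ss`` count each qualifying edge once.  Triples are counted with
    the centred, ordered-ends convention: for a middle node b,

    * [ABC] with A ≠ C contributes (#A-neighbours of b) · (#C-neighbours),
    * [ABA] contributes (#A-neighbours) · (#A-neighbours − 1),

    summed over all b in state B.  Under this convention the pair closure
    [ISI] ≈ [SI]²/[S] and [SSI] ≈ 2[SS][SI]/[S] (multiplicities m(A,B)=2 for
    A=B, 1 otherwise) is the asymptotically consistent estimator.
    """

    s: int
    i: int
    r: int
    x: int
    si: int
    ss: int
    ssi: int
    isi: int

    @property
    def n(self) -> int:
        return self.s + self.i + self.r + self.x


class NetworkState:
    """Mutable node states + adjacency with exact S–I / S–S link caches.

    The graph is simple (no self-loops, no multi-edges).  All state and
    topology mutations must go through :meth:`set_state`,
    :meth:`remove_edge` and :meth:`add_edge`, which keep the caches exact.
    S–I links are stored as ordered ``(s_node, i_node)`` tuples, S–S links
    as ``(min, max)`` tuples.
    """

    __slots__ = ("n", "adj", "node_state", "by_state", "si_links", "ss_links", "n_edges")

    def __init__(self, adj: list[set[int]], states=None):
        self.n = len(adj)
        self.adj = adj
        if states is None:
            self.node_state = [S] * self.n
        else:
            self.node_state = [
                _LABEL_TO_CODE[s] if isinstance(s, str) else int(s) for s in states
            ]
        self.rebuild_caches()

    # -- construction ---------------------------------------------------

    @classmethod
    def from_networkx(cls, graph: nx.Graph, states=None) -> "NetworkState":
        n = graph.number_of_nodes()
        adj = [set() for _ in range(n)]
        for u, v in graph.edges():
            if u == v:
                continue
            adj[u].add(v)
            adj[v].add(u)
        return cls(adj, states)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        for u in range((self.n)):
            for v in self.adj[u]:
                if u < v:
                    g.add_edge(u, v)
        return g

    def copy(self) -> "NetworkState":
        return NetworkState([set(a) for a in self.adj], list(self.node_state))

    # -- cache maintenance ----------------------------------------------

    def rebuild_caches(self) -> None:
        """Recompute state sets, link caches and edge count from scratch."""
        st = self.node_state
        self.by_state = [IndexedSet() for _ in range(4)]
        for v in range(self.n):
            self.by_state[st[v]].add(v)
        self.si_links = IndexedSet()
        self.ss_links = IndexedSet()
        m = 0
        for u in range(self.n):
            su = st[u]
            for v in self.adj[u]:
                if v <= u:
                    continue
                m += 1
                sv = st[v]
                if su == S and sv == S:
                    self.ss_links.add((u, v))
                elif su == S and sv == I:
                    self.si_links.add((u, v))
                elif su == I and sv == S:
                    self.si_links.add((v, u))
        self.n_edges = m

    def _pair_discard(self, v: int, sv: int, u: int, su: int) -> None:
        if sv == S:
            if su == S:
                self.ss_links.discard((v, u) if v < u else (u, v))
            elif su == I:
                self.si_links.discard((v, u))
        elif sv == I and su == S:
            self.si_links.discard((u, v))

    def _pair_add(self, v: int, sv: int, u: int, su: int) -> None:
        if sv == S:
            if su == S:
                self.ss_links.add((v, u) if v < u else (u, v))
            elif su == I:
                self.si_links.add((v, u))
        elif sv == I and su == S:
            self.si_links.add((u, v))

    # -- mutations -------------------------------------------------------

    def set_state(self, v: int, new_state: int) -> None:
        """Relabel node v, updating link caches in O(degree)."""
        old = self.node_state[v]
        if old == new_state:
            return
        st = self.node_state
        for u in self.adj[v]:
            self._pair_discard(v, old, u, st[u])
        st[v] = new_state
        self.by_state[old].discard(v)
        self.by_state[new_state].add(v)
        for u in self.adj[v]:
            self._pair_add(v, new_state, u, st[u])

    def remove_edge(self, u: int, v: int) -> None:
        self.adj[u].discard(v)
        self.adj[v].discard(u)
        self._pair_discard(u, self.node_state[u], v, self.node_state[v])
        self.n_edges -= 1

    def add_edge(self, u: int, v: int) -> None:
        if u == v or v in self.adj[u]:
            raise ValueError(f"edge ({u},{v}) would break graph simplicity")
        self.adj[u].add(v)
        self.adj[v].add(u)
        self._pair_add(u, self.node_state[u], v, self.node_state[v])
        self.n_edges += 1

    # -- observables -----------------------------------------------------

    def counts(self) -> tuple[int, int, int, int, int, int]:
        """(#S, #I, #R, #X, |SI|, |SS|) from the incremental caches."""
        b = self.by_state
        return (len(b[S]), len(b[I]), len(b[R]), len(b[X]),
                len(self.si_links), len(self.ss_links))

    @property
    def states(self) -> dict[int, str]:
        """Node-id → state-label mapping (snapshot view)."""
        return {v: STATE_LABELS[s] for v, s in enumerate(self.node_state)}

    @property
    def edges(self) -> set[tuple[int, int]]:
        return {(u, v) for u in range(self.n) for v in self.adj[u] if u < v}

    def validate(self) -> None:
        """Full consistency check: simplicity, symmetry, caches vs recount.

        Raises ``ValueError`` on the first violated invariant.  Intended
        for tests and debugging; O(N + M).
        """
        st = self.node_state
        m = 0
        si, ss = set(), set()
        for u in range(self.n):
            if u in self.adj[u]:
                raise ValueError(f"self-loop at node {u}")
            for v in self.adj[u]:
                if u not in self.adj[v]:
                    raise ValueError(f"asymmetric edge ({u},{v})")
                if v <= u:
                    continue
                m += 1
                pair = {st[u], st[v]}
                if pair == {S}:
                    ss.add((u, v))
                elif pair == {S, I}:
                    si.add((u, v) if st[u] == S else (v, u))
        if m != self.n_edges:
            raise ValueError(f"edge count cache {self.n_edges} != recount {m}")
        if si != self.si_links.as_set():
            raise ValueError("si_links cache diverged from recount")
        if ss != self.ss_links.as_set():
            raise ValueError("ss_links cache diverged from recount")
        for k in range(4):
            expected = {v for v in range(self.n) if st[v] == k}
            if expected != self.by_state[k].as_set():
                raise ValueError(f"state-set cache for {STATE_LABELS[k]} diverged")


def generate_er_graph(config: NetworkConfig) -> NetworkState:
    """Sample G(N, p) with p = μ/(N−1); all nodes start susceptible.

    Deterministic given ``config.seed``.  With this p the expected edge
    count is Nμ/2 and the expected degree is exactly μ.
    """
    p = config.mean_degree / (config.n_nodes - 1)
    g = nx.fast_gnp_random_graph(config.n_nodes, p, seed=config.seed)
    return NetworkState.from_networkx(g)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def initialize_states(net: NetworkState, rho_i0: float, seed) -> NetworkState:
    """Infect exactly round(rho_i0 · N) uniformly chosen nodes, rest S.

    Rounds half away from zero so that e.g. 1% of 2000 gives exactly 20
    seeds.  Mutates ``net`` in place (resetting any previous labels) and
    returns it with link caches rebuilt.
    """
    if not 0.0 <= rho_i0 <= 1.0:
        raise ValueError("rho_i0 must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = _round_half_away(rho_i0 * net.n)
    net.node_state = [S] * net.n
    if k > 0:
        for v in rng.choice(net.n, size=k, replace=False):
            net.node_state[int(v)] = I
    net.rebuild_caches()
    return net


def count_motifs(net: NetworkState) -> MotifCounts:
    """Exact recount of nodes, S–I/S–S links and SSI/ISI centred triples.

    Independent of the incremental caches (used to validate them).  Runs in
    O(N + M) using per-node neighbour-state tallies.
    """
    st = net.node_state
    ns = [0, 0, 0, 0]
    for s in st:
        ns[s] += 1
    si = ss = ssi = isi = 0
    for b in range(net.n):
        if st[b] != S:
            continue
        n_s = n_i = 0
        for u in net.adj[b]:
            su = st[u]
            if su == S:
                n_s += 1
                if u > b:
                    ss += 1
            elif su == I:
                n_i += 1
                si += 1
        ssi += n_s * n_i
        isi += n_i * (n_i - 1)
    return MotifCounts(s=ns[S], i=ns[I], r=ns[R], x=ns[X],
                       si=si, ss=ss, ssi=ssi, isi=isi)


def write_edge_list(net: NetworkState, path) -> None:
    """Plain-text edge list: two whitespace-separated node ids per line."""
    with open(path, "w") as fh:
        for u, v in sorted(net.edges):
            fh.write(f"{u} {v}\n")


def write_node_states(net: NetworkState, path) -> None:
    """Node-state snapshot as CSV with columns node_id,state."""
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["node_id", "state"])
        for v in range(net.n):
            wr.writerow([v, STATE_LABELS[net.node_state[v]]])
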