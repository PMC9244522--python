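import numpy as np
import pytest

from sirxnet.network import NetworkState


def build_net(n, edges, states):
    """Small NetworkState from an explicit edge list and state string."""
    adj = [set() for _ in range(n)]
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return NetworkState(adj, list(states))


def brute_force_motifs(net):
    """Exhaustive motif counts by enumeration over nodes, edges and
    centred ordered-ends triples; the independent oracle for count_motifs."""
    from sirxnet.network import S, I, STATE_LABELS

    st = net.node_state
    lab = [STATE_LABELS[s] for s in st]
    counts = {c: lab.count(c) for c in "SIRX"}
    si = ss = 0
    for u in range(net.n):
        for v in net.adj[u]:
            if u < v:
                pair = {lab[u], lab[v]}
                if pair == {"S"}:
                    ss += 1
                elif pair == {"S", "I"}:
                    si += 1
    ssi = isi = 0
    for b in range(net.n):
        if lab[b] != "S":
            continue
        for a in net.adj[b]:
            for c in net.adj[b]:
                if a == c:
                    continue
                if lab[a] == "S" and lab[c] == "I":
                    ssi += 1
                if lab[a] == "I" and lab[c] == "I":
                    isi += 1
    return counts["S"], counts["I"], counts["R"], counts["X"], si, ss, ssi, isi


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
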