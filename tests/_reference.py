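"""Independent brute-force reference implementations used as test oracles.

Everything here is written with explicit Python loops over neighbor sets,
deliberately sharing no code with the package's vectorized encoder.
"""

import numpy as np

from cgrnet.featurizer import FeaturizedGraph


def relu(x):
    return np.maximum(x, 0.0)


def brute_force_edge_states(graph, weights, depth):
    """Directed edge states after ``depth`` message-passing steps.

    Returns a dict keyed by (source_atom, target_atom). The incoming sum
    for edge (v, w) runs over neighbors k of v with k != w, using the
    states of edges (k, v).
    """
    M = graph.n_directed_edges
    edges = [(int(graph.edge_src[e]), int(graph.edge_tgt[e]))
             for e in range(M)]
    h0 = {}
    for e, (v, w) in enumerate(edges):
        x = np.concatenate([graph.atom_matrix[v], graph.edge_matrix[e]])
        h0[(v, w)] = relu(weights["W_i"] @ x)
    h = dict(h0)
    hidden = weights["W_h"].shape[0]
    for _ in range(depth):
        new = {}
        for (v, w) in edges:
            s = np.zeros(hidden)
            for (k, tgt) in edges:
                if tgt == v and k != w:
                    s = s + h[(k, v)]
            new[(v, w)] = relu(h0[(v, w)] + weights["W_h"] @ s
                               + weights["b_h"])
        h = new
    return h


def brute_force_atom_states(graph, weights, depth):
    h = brute_force_edge_states(graph, weights, depth)
    hidden = weights["W_h"].shape[0]
    out = []
    for v in range(graph.n_atoms):
        s = np.zeros(hidden)
        for (k, tgt), state in h.items():
            if tgt == v:
                s = s + state
        x = np.concatenate([graph.atom_matrix[v], s])
        out.append(relu(weights["W_o"] @ x + weights["b_o"]))
    return np.stack(out) if out else np.zeros((0, hidden))


def brute_force_embedding(graph, weights, depth, aggregation="mean"):
    atoms = brute_force_atom_states(graph, weights, depth)
    emb = atoms.mean(axis=0) if aggregation == "mean" else atoms.sum(axis=0)
    if graph.extra_features is not None:
        emb = np.concatenate([emb, graph.extra_features])
    return emb


def random_graph(rng, max_atoms=8, atom_dim=12, bond_dim=5,
                 with_extra=False):
    """A random connected featurized graph (tree plus chords)."""
    n = int(rng.integers(2, max_atoms + 1))
    edges = set()
    for v in range(1, n):
        u = int(rng.integers(0, v))
        edges.add((u, v))
    for _ in range(int(rng.integers(0, n))):
        u, v = rng.integers(0, n, size=2)
        if u != v:
            edges.add((min(int(u), int(v)), max(int(u), int(v))))
    edges = sorted(edges)
    src, tgt, rev = [], [], []
    for k, (u, v) in enumerate(edges):
        src += [u, v]
        tgt += [v, u]
        rev += [2 * k + 1, 2 * k]
    return FeaturizedGraph(
        atom_matrix=rng.standard_normal((n, atom_dim)),
        edge_matrix=np.repeat(rng.standard_normal((len(edges), bond_dim)),
                              2, axis=0),
        edge_src=np.array(src), edge_tgt=np.array(tgt),
        rev_index=np.array(rev),
        extra_features=rng.standard_normal(3) if with_extra else None)
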