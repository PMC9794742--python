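"""Independent brute-force oracles used by the tests.

These deliberately re-derive results through a different route than the
package (plain dynamic programming, exhaustive enumeration, closed forms)
so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_local_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Quadratic Gotoh local-alignment optimum with BLAST-convention affine
    gaps: a gap of length k costs gap_open + k * gap_extend."""
    open_cost = gap_open + gap_extend
    n, m = len(a), len(b)
    neg = -1e9
    h_prev = np.zeros(m + 1)
    e_prev = np.full(m + 1, neg)
    best = 0.0
    for i in range(1, n + 1):
        h_cur = np.zeros(m + 1)
        e_cur = np.full(m + 1, neg)
        f = neg
        for j in range(1, m + 1):
            e_cur[j] = max(h_prev[j] - open_cost, e_prev[j] - gap_extend)
            f = max(h_cur[j - 1] - open_cost, f - gap_extend)
            diag = h_prev[j - 1] + _BLOSUM62[a[i - 1], b[j - 1]]
            h_cur[j] = max(0.0, diag, e_cur[j], f)
            best = max(best, h_cur[j])
        h_prev, e_prev = h_cur, e_cur
    return best


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """A random binary unrooted tree; returns (newick-ish structure, D).

    Built by sequential random joins; leaf-to-leaf path lengths give an
    exactly additive distance matrix.
    """
    labels = [f"t{i}" for i in range(n_leaves)]
    # adjacency with branch lengths
    next_id = n_leaves
    nodes = list(range(n_leaves))
    edges: dict[tuple[int, int], float] = {}

    def connect(u, v, w):
        edges[(u, v)] = w
        edges[(v, u)] = w

    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        u, v = nodes[i], nodes[j]
        parent = next_id
        next_id += 1
        connect(u, parent, float(rng.uniform(0.05, 1.0)))
        connect(v, parent, float(rng.uniform(0.05, 1.0)))
        nodes = [x for x in nodes if x not in (u, v)] + [parent]
    connect(nodes[0], nodes[1], float(rng.uniform(0.05, 1.0)))

    adj: dict[int, list[tuple[int, float]]] = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))

    def dists_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in out:
                    out[v] = out[u] + w
                    stack.append(v)
        return out

    d = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        di = dists_from(i)
        for j in range(n_leaves):
            d[i, j] = di[j]
    d = (d + d.T) / 2.0  # exact symmetry despite float summation order
    splits = _tree_splits_from_edges(adj, n_leaves, labels)
    return labels, d, splits


def _tree_splits_from_edges(adj, n_leaves, labels):
    """Non-trivial splits of the generating tree (frozensets of leaf names,
    normalised to the side without labels[0])."""
    splits = set()
    universe = frozenset(labels)
    for u in adj:
        for v, _ in adj[u]:
            if u > v:
                continue
            # leaves reachable from v without crossing u
            seen = {u, v}
            stack = [v]
            side = set()
            while stack:
                x = stack.pop()
                if x < n_leaves:
                    side.add(labels[x])
                for y, _ in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            if 1 < len(side) < n_leaves - 1:
                fs = frozenset(side)
                if labels[0] in fs:
                    fs = universe - fs
                splits.add(fs)
    return splits


def exhaustive_group_count(seqs: dict[str, str], threshold: float, identity_fn) -> int:
    """Cluster count oracle for well-separated fixtures: connected components
    of the >= threshold identity graph (equals any greedy order's count when
    within-group identities all pass and between-group all fail)."""
    names = sorted(seqs)
    parent = {n: n for n in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(names, 2):
        if identity_fn(seqs[a], seqs[b]) >= threshold:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    return len({find(n) for n in names})
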