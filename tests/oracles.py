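"""Independent brute-force oracles for network statistics.

Everything here enumerates all simple paths with itertools — exponential,
for graphs of at most ~8 nodes — and recomputes each statistic from its
definition, sharing no code with skillnet.metrics.
"""
from itertools import permutations

import numpy as np

TIE_TOL = 1e-12


def _tie(a, b):
    return abs(a - b) <= TIE_TOL * max(1.0, abs(a), abs(b))


def all_simple_paths(W, s, t):
    """All simple s-t paths (as node tuples) in the graph of nonzero |W|."""
    p = W.shape[0]
    others = [v for v in range(p) if v not in (s, t)]
    paths = []
    for k in range(len(others) + 1):
        for mid in permutations(others, k):
            path = (s, *mid, t)
            if all(W[path[i], path[i + 1]] != 0 for i in range(len(path) - 1)):
                paths.append(path)
    return paths


def path_length(W, path):
    return sum(1.0 / abs(W[path[i], path[i + 1]]) for i in range(len(path) - 1))


def shortest_paths(W, s, t):
    """(distance, list of shortest paths); (inf, []) if unreachable."""
    paths = all_simple_paths(W, s, t)
    if not paths:
        return np.inf, []
    lengths = [path_length(W, q) for q in paths]
    d = min(lengths)
    return d, [q for q, l in zip(paths, lengths) if _tie(l, d)]


def distance_matrix(W):
    p = W.shape[0]
    D = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            D[i, j] = D[j, i] = shortest_paths(W, i, j)[0]
    return D


def betweenness(W, pair_ok=lambda j, k: True, fractional=True):
    """Brute-force betweenness over unordered pairs passing ``pair_ok``."""
    p = W.shape[0]
    bc = np.zeros(p)
    for j in range(p):
        for k in range(j + 1, p):
            if not pair_ok(j, k):
                continue
            _, sps = shortest_paths(W, j, k)
            if not sps:
                continue
            for i in range(p):
                if i in (j, k):
                    continue
                on = sum(1 for q in sps if i in q)
                if fractional:
                    bc[i] += on / len(sps)
                elif on:
                    bc[i] += 1.0
    return bc


def strength(W):
    return np.abs(W).sum(axis=1)


def closeness(W):
    D = distance_matrix(W)
    p = W.shape[0]
    out = np.zeros(p)
    for i in range(p):
        d = [D[i, j] for j in range(p) if j != i and np.isfinite(D[i, j])]
        out[i] = 1.0 / sum(d) if d else 0.0
    return out


def bridge_strength(W, comm):
    p = W.shape[0]
    return np.array(
        [sum(abs(W[i, j]) for j in range(p) if comm[j] != comm[i]) for i in range(p)]
    )


def bridge_closeness(W, comm):
    D = distance_matrix(W)
    p = W.shape[0]
    out = np.zeros(p)
    for i in range(p):
        d = [D[i, j] for j in range(p) if comm[j] != comm[i] and np.isfinite(D[i, j]) and j != i]
        out[i] = 1.0 / (sum(d) / len(d)) if d else 0.0
    return out
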