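"""Centrality and bridge centrality on signed weighted skill networks.

All statistics use absolute edge weights.  Shortest paths use Dijkstra on
edge lengths 1/|w| (strong partial correlations are short distances).
Conventions, chosen to match the bridge-centrality literature for
psychometric networks:

* strength          sum of |w| over all neighbours
* closeness         1 / (sum of shortest-path distances to reachable nodes)
* betweenness       Brandes fractional credit over unordered node pairs
* bridge strength   sum of |w| to the other community
* bridge closeness  1 / (mean distance to reachable out-community nodes)
* bridge betweenness  betweenness restricted to cross-community pairs

Closeness inverts a SUM while bridge closeness inverts a MEAN; the
asymmetry is deliberate and mirrors the reference software.  Unreachable
nodes are excluded from the sums; a node with nothing reachable scores 0.
Equal-length shortest paths share credit fractionally; an integer
"count all" mode (every node on any tied shortest path gets full credit)
is available for cross-checks.  Path-length ties are resolved with a
relative tolerance of 1e-12.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _dijkstra

from .errors import ValidationError

__all__ = [
    "NetworkGraph",
    "strength",
    "bridge_strength",
    "shortest_path_distances",
    "closeness",
    "bridge_closeness",
    "betweenness",
    "bridge_betweenness",
    "centrality_table",
    "STATISTICS",
]

TIE_TOL = 1e-12
STATISTICS = (
    "strength",
    "closeness",
    "betweenness",
    "bridge_strength",
    "bridge_closeness",
    "bridge_betweenness",
)


@dataclass
class NetworkGraph:
    """Signed weighted undirected network with a fixed 2-community split."""

    W: np.ndarray
    labels: tuple[str, ...]
    community_of: dict[str, str]

    @classmethod
    def from_fit(cls, fit, community_of: dict[str, str]) -> "NetworkGraph":
        return cls(W=fit.W, labels=fit.labels, community_of=dict(community_of))

    @property
    def p(self) -> int:
        return len(self.labels)

    @property
    def communities(self) -> np.ndarray:
        return np.array([self.community_of[l] for l in self.labels])

    def validate(self) -> None:
        W = self.W
        if W.shape != (self.p, self.p):
            raise ValidationError("weight matrix shape does not match labels")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValidationError("weight matrix must be symmetric")
        if np.abs(np.diag(W)).max(initial=0.0) != 0.0:
            raise ValidationError("weight matrix must have zero diagonal")
        missing = [l for l in self.labels if l not in self.community_of]
        if missing:
            raise ValidationError(f"labels without community: {missing}")

    def _require_two_communities(self) -> None:
        if len(set(self.community_of[l] for l in self.labels)) < 2:
            raise ValidationError("bridge statistics need two nonempty communities")


def _lengths(G: NetworkGraph) -> np.ndarray:
    A = np.abs(G.W)
    with np.errstate(divide="ignore"):
        L = np.where(A > 0, 1.0 / A, 0.0)
    return L


def _tie(a: float, b: float) -> bool:
    return abs(a - b) <= TIE_TOL * max(1.0, abs(a), abs(b))


def strength(G: NetworkGraph) -> np.ndarray:
    G.validate()
    return np.abs(G.W).sum(axis=1)


def bridge_strength(G: NetworkGraph) -> np.ndarray:
    G.validate()
    G._require_two_communities()
    comm = G.communities
    cross = comm[:, None] != comm[None, :]
    return (np.abs(G.W) * cross).sum(axis=1)


def shortest_path_distances(G: NetworkGraph) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Dijkstra distances and shortest-path counts.

    Returns ``(D, sigma)``: ``D[i, j]`` the shortest-path length on edge
    lengths 1/|w| (inf if unreachable), ``sigma[i, j]`` the number of
    distinct shortest paths (0 if unreachable, 1 on the diagonal).
    """
    G.validate()
    L = _lengths(G)
    D = _dijkstra(csr_matrix(L), directed=False)
    p = G.p
    sigma = np.zeros((p, p))
    for s in range(p):
        order = np.argsort(D[s], kind="stable")
        sig = np.zeros(p)
        sig[s] = 1.0
        for v in order:
            if v == s or not np.isfinite(D[s, v]):
                continue
            tot = 0.0
            for u in range(p):
                if L[u, v] > 0 and np.isfinite(D[s, u]) and _tie(D[s, u] + L[u, v], D[s, v]):
                    tot += sig[u]
            sig[v] = tot
        sigma[s] = sig
    return D, sigma


def _sssp(L: np.ndarray, D_s: np.ndarray):
    """Single-source shortest-path DAG: visit order, sigma, predecessor lists."""
    p = L.shape[0]
    s = int(np.argmin(D_s))
    order = [v for v in np.argsort(D_s, kind="stable") if np.isfinite(D_s[v])]
    sigma = np.zeros(p)
    sigma[s] = 1.0
    preds: list[list[int]] = [[] for _ in range(p)]
    for v in order:
        if v == s:
            continue
        tot = 0.0
        for u in range(p):
            if L[u, v] > 0 and np.isfinite(D_s[u]) and _tie(D_s[u] + L[u, v], D_s[v]):
                preds[v].append(u)
                tot += sigma[u]
        sigma[v] = tot
    return order, sigma, preds


def _brandes(G: NetworkGraph, cross_only: bool) -> np.ndarray:
    """Fractional betweenness over unordered pairs (optionally cross-community)."""
    p = G.p
    L = _lengths(G)
    D = _dijkstra(csr_matrix(L), directed=False)
    comm = G.communities
    bc = np.zeros(p)
    for s in range(p):
        order, sigma, preds = _sssp(L, D[s])
        is_target = np.ones(p, dtype=bool)
        is_target[s] = False
        if cross_only:
            is_target &= comm != comm[s]
        delta = np.zeros(p)
        for w in reversed(order):
            if w == s:
                continue
            coeff = (1.0 if is_target[w] else 0.0) + delta[w]
            for u in preds[w]:
                delta[u] += sigma[u] / sigma[w] * coeff
        delta[s] = 0.0
        bc += delta
    return bc / 2.0  # each unordered pair visited from both endpoints


def _count_all(G: NetworkGraph, cross_only: bool) -> np.ndarray:
    """Integer-credit variant: full credit to every node on any tied path."""
    p = G.p
    D, _ = shortest_path_distances(G)
    comm = G.communities
    bc = np.zeros(p)
    for j in range(p):
        for k in range(j + 1, p):
            if not np.isfinite(D[j, k]):
                continue
            if cross_only and comm[j] == comm[k]:
                continue
            for i in range(p):
                if i in (j, k):
                    continue
                if np.isfinite(D[j, i]) and np.isfinite(D[i, k]) and _tie(
                    D[j, i] + D[i, k], D[j, k]
                ):
                    bc[i] += 1.0
    return bc


def betweenness(G: NetworkGraph, mode: str = "fractional") -> np.ndarray:
    G.validate()
    if mode == "fractional":
        return _brandes(G, cross_only=False)
    if mode == "count_all":
        return _count_all(G, cross_only=False)
    raise ValidationError(f"unknown betweenness mode {mode!r}")


def bridge_betweenness(G: NetworkGraph, mode: str = "fractional") -> np.ndarray:
    G.validate()
    G._require_two_communities()
    if mode == "fractional":
        return _brandes(G, cross_only=True)
    if mode == "count_all":
        return _count_all(G, cross_only=True)
    raise ValidationError(f"unknown betweenness mode {mode!r}")


def closeness(G: NetworkGraph) -> np.ndarray:
    """Inverse sum of shortest-path distances to reachable nodes."""
    G.validate()
    D, _ = shortest_path_distances(G)
    p = G.p
    out = np.zeros(p)
    for i in range(p):
        d = D[i]
        reach = np.isfinite(d) & (np.arange(p) != i)
        if reach.any():
            out[i] = 1.0 / d[reach].sum()
    return out


def bridge_closeness(G: NetworkGraph) -> np.ndarray:
    """Inverse mean distance to reachable nodes of the other community."""
    G.validate()
    G._require_two_communities()
    D, _ = shortest_path_distances(G)
    comm = G.communities
    p = G.p
    out = np.zeros(p)
    for i in range(p):
        mask = (comm != comm[i]) & np.isfinite(D[i]) & (np.arange(p) != i)
        if mask.any():
            out[i] = 1.0 / D[i][mask].mean()
    return out


def _all_centralities(G: NetworkGraph) -> dict[str, np.ndarray]:
    """All six statistics sharing one Dijkstra and one Brandes pass."""
    p = G.p
    L = _lengths(G)
    D = _dijkstra(csr_matrix(L), directed=False)
    comm = G.communities
    A = np.abs(G.W)
    cross = comm[:, None] != comm[None, :]
    idx = np.arange(p)
    clo = np.zeros(p)
    bclo = np.zeros(p)
    for i in range(p):
        reach = np.isfinite(D[i]) & (idx != i)
        if reach.any():
            clo[i] = 1.0 / D[i][reach].sum()
        creach = reach & cross[i]
        if creach.any():
            bclo[i] = 1.0 / D[i][creach].mean()
    bt = np.zeros(p)
    bbt = np.zeros(p)
    for s in range(p):
        order, sigma, preds = _sssp(L, D[s])
        delta = np.zeros(p)
        bdelta = np.zeros(p)
        for w in reversed(order):
            if w == s:
                continue
            c = 1.0 + delta[w]
            bc = (1.0 if cross[s, w] else 0.0) + bdelta[w]
            for u in preds[w]:
                ratio = sigma[u] / sigma[w]
                delta[u] += ratio * c
                bdelta[u] += ratio * bc
        delta[s] = bdelta[s] = 0.0
        bt += delta
        bbt += bdelta
    return {
        "strength": A.sum(axis=1),
        "closeness": clo,
        "betweenness": bt / 2.0,
        "bridge_strength": (A * cross).sum(axis=1),
        "bridge_closeness": bclo,
        "bridge_betweenness": bbt / 2.0,
    }


def centrality_table(G: NetworkGraph, mode: str = "fractional") -> pd.DataFrame:
    """All six statistics per node, in the graph's node order."""
    G.validate()
    G._require_two_communities()
    if mode == "fractional":
        cols = _all_centralities(G)
    elif mode == "count_all":
        cols = {
            "strength": strength(G),
            "closeness": closeness(G),
            "betweenness": betweenness(G, mode=mode),
            "bridge_strength": bridge_strength(G),
            "bridge_closeness": bridge_closeness(G),
            "bridge_betweenness": bridge_betweenness(G, mode=mode),
        }
    else:
        raise ValidationError(f"unknown betweenness mode {mode!r}")
    return pd.DataFrame(
        {"community": G.communities, **cols},
        index=pd.Index(G.labels, name="node"),
    )
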