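"""Brute-force reference implementations used only by the test suite.

These deliberately use the most literal formulation available — explicit
path enumeration, BFS distance sums, dense eigendecomposition, direct
induced-subgraph counting, combinatorial draw enumeration — and share no
code with the package implementations they check.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np


def bc_oracle(g: nx.Graph) -> dict:
    """Betweenness by enumerating every shortest path of every pair."""

    def all_paths(s, t):
        found = []

        def dfs(path):
            u = path[-1]
            if u == t:
                found.append(list(path))
                return
            for w in g[u]:
                if w not in path:
                    path.append(w)
                    dfs(path)
                    path.pop()

        dfs([s])
        return found

    bc = dict.fromkeys(g, 0.0)
    for s, t in itertools.combinations(list(g), 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        d = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == d]
        for v in g:
            if v in (s, t):
                continue
            bc[v] += sum(v in p for p in shortest) / len(shortest)
    return bc


def cc_oracle(g: nx.Graph) -> dict:
    out = {}
    for v in g:
        lengths = nx.single_source_shortest_path_length(g, v)
        reached = len(lengths) - 1
        out[v] = reached / sum(lengths.values()) if reached else 0.0
    return out


def ec_oracle(g: nx.Graph) -> dict:
    """Principal eigenvector from a dense symmetric eigensolver."""
    nodes = sorted(g)
    a = nx.to_numpy_array(g, nodelist=nodes)
    _, vecs = np.linalg.eigh(a)
    vec = vecs[:, -1]
    if vec.sum() < 0:
        vec = -vec
    return dict(zip(nodes, np.abs(vec)))


def dc_oracle(g: nx.Graph) -> dict:
    a = nx.to_numpy_array(g, nodelist=sorted(g))
    return dict(zip(sorted(g), a.sum(axis=1)))


def lac_oracle(g: nx.Graph) -> dict:
    out = {}
    for v in g:
        nbrs = list(g[v])
        if not nbrs:
            out[v] = 0.0
            continue
        sub = g.subgraph(nbrs)
        out[v] = sum(d for _, d in sub.degree()) / len(nbrs)
    return out


def nc_oracle(g: nx.Graph) -> dict:
    out = {}
    for v in g:
        total = 0.0
        for u in g[v]:
            denom = min(g.degree(v) - 1, g.degree(u) - 1)
            if denom > 0:
                common = len(set(g[v]) & set(g[u]))
                total += common / denom
        out[v] = total
    return out


CENTRALITY_ORACLES = {
    "bc": bc_oracle,
    "cc": cc_oracle,
    "dc": dc_oracle,
    "ec": ec_oracle,
    "lac": lac_oracle,
    "nc": nc_oracle,
}


def connected_atlas(max_nodes: int = 7):
    """All non-isomorphic connected graphs with 2..max_nodes nodes,
    relabelled to string node ids."""
    out = []
    for graph in nx.graph_atlas_g():
        if 2 <= graph.number_of_nodes() <= max_nodes and nx.is_connected(graph):
            out.append(nx.relabel_nodes(graph, {i: f"N{i}" for i in graph}))
    return out


def venn_oracle(named_sets: dict[str, set[str]]) -> dict[frozenset, set[str]]:
    """Region assignment by per-symbol membership enumeration."""
    labels = list(named_sets)
    regions: dict[frozenset, set[str]] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            regions[frozenset(combo)] = set()
    union = set().union(*named_sets.values())
    for symbol in union:
        membership = frozenset(l for l in labels if symbol in named_sets[l])
        regions[membership].add(symbol)
    return regions


def hypergeom_enum(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by literally enumerating every size-n draw (small N only)."""
    marked = set(range(K))
    total = hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total if total else 1.0


def hypergeom_comb(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by direct binomial-coefficient counting."""
    total = math.comb(N, n)
    hits = sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    )
    return hits / total


def bh_oracle(pvalues: list[float]) -> list[float]:
    """Literal BH step-up: padj_(i) = min_{j >= i} m * p_(j) / j, capped."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvalues[i] / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted
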