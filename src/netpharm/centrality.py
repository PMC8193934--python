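"""The six node-centrality features used for hub-gene extraction.

All six are implemented here from first principles on simple undirected
graphs:

- DC, degree centrality: raw neighbor count ``|N(v)|``.
- BC, betweenness centrality: unnormalized sum over unordered pairs
  ``{s, t}`` (``s != t != v``) of the fraction of shortest s-t paths passing
  through ``v``, accumulated with Brandes' dependency algorithm.
- CC, closeness centrality: ``(|C_v| - 1) / sum of distances`` within v's
  connected component ``C_v`` (0 for singleton components); values in [0, 1].
- EC, eigenvector centrality: the non-negative principal eigenvector of the
  adjacency matrix, unit Euclidean norm.
- LAC, local average connectivity: mean degree of v's neighbors inside the
  subgraph they induce (v excluded).
- NC, network centrality: the sum over v's edges of the edge clustering
  coefficient ``ECC(v, u) = z_vu / min(deg(v) - 1, deg(u) - 1)`` where
  ``z_vu`` counts common neighbors; ECC is 0 when the denominator is 0
  (pendant edges).

Raw (unnormalized) BC and count-scale DC are the defaults because that is
the scale hub-filter medians are naturally reported on for interactome
subnetworks; pass ``normalized=True`` to :func:`centrality_table` for the
``(n-1)(n-2)/2``- and ``(n-1)``-rescaled variants.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConvergenceError, ValidationError

FEATURES = ("bc", "cc", "dc", "ec", "lac", "nc")


def degree_centrality(g: nx.Graph) -> dict[str, float]:
    """Raw degree: DC(v) = |N(v)|."""
    return {v: float(d) for v, d in g.degree()}


def betweenness_centrality(g: nx.Graph) -> dict[str, float]:
    """Unnormalized betweenness over unordered pairs (Brandes accumulation)."""
    bc = dict.fromkeys(g, 0.0)
    for s in g:
        # single-source shortest-path DAG (BFS; unweighted)
        stack: list = []
        preds: dict = {v: [] for v in g}
        sigma = dict.fromkeys(g, 0.0)
        sigma[s] = 1.0
        dist = dict.fromkeys(g, -1)
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in g[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        # back-propagation of pair dependencies
        delta = dict.fromkeys(g, 0.0)
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # each unordered pair was accumulated from both endpoints
    return {v: val / 2.0 for v, val in bc.items()}


def closeness_centrality(g: nx.Graph) -> dict[str, float]:
    """Component-restricted closeness in [0, 1]; 0 for isolated nodes."""
    cc: dict[str, float] = {}
    for v in g:
        dist = {v: 0}
        queue = deque([v])
        total = 0
        while queue:
            u = queue.popleft()
            for w in g[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    total += dist[w]
                    queue.append(w)
        reached = len(dist) - 1
        cc[v] = reached / total if reached > 0 else 0.0
    return cc


def eigenvector_centrality(
    g: nx.Graph, tol: float = 1e-10, max_iter: int = 10000
) -> dict[str, float]:
    """Principal adjacency eigenvector, non-negative, unit Euclidean norm.

    Power iteration runs on ``A + I`` (same eigenvectors as ``A``; the unit
    shift makes the Perron root strictly dominant so that bipartite graphs,
    whose adjacency spectrum is sign-symmetric, converge too) starting from
    the uniform positive vector. Convergence is successive-iterate max-norm
    difference below ``tol``.
    """
    if g.number_of_edges() == 0:
        raise ValidationError("eigenvector centrality needs at least one edge")
    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, dtype=float)
    m = a + np.eye(len(nodes))
    x = np.full(len(nodes), 1.0 / np.sqrt(len(nodes)))
    for _ in range(max_iter):
        y = m @ x
        y /= np.linalg.norm(y)
        if np.max(np.abs(y - x)) < tol:
            return dict(zip(nodes, y.tolist()))
        x = y
    raise ConvergenceError(
        f"eigenvector centrality did not converge in {max_iter} iterations "
        f"on a graph with {len(nodes)} nodes"
    )


def local_average_connectivity(g: nx.Graph) -> dict[str, float]:
    """LAC(v): average degree of N(v) within the subgraph induced by N(v)."""
    lac: dict[str, float] = {}
    for v in g:
        nbrs = set(g[v])
        if not nbrs:
            lac[v] = 0.0
            continue
        # sum over w in N(v) of deg_{G[N(v)]}(w) = twice the induced edge count
        total = sum(1 for w in nbrs for u in g[w] if u in nbrs)
        lac[v] = total / len(nbrs)
    return lac


def network_centrality(g: nx.Graph) -> dict[str, float]:
    """NC(v): sum of edge clustering coefficients over v's incident edges."""
    nc: dict[str, float] = {}
    adj = {v: set(g[v]) for v in g}
    for v in g:
        dv = len(adj[v])
        total = 0.0
        for u in adj[v]:
            denom = min(dv - 1, len(adj[u]) - 1)
            if denom > 0:
                total += len(adj[v] & adj[u]) / denom
        nc[v] = total
    return nc


@dataclass(frozen=True)
class CentralityTable:
    """Per-node values of the six features for one graph snapshot."""

    frame: pd.DataFrame
    snapshot_id: str = ""

    def medians(self) -> dict[str, float]:
        return {f: float(self.frame[f].median()) for f in FEATURES}


def centrality_table(
    g: nx.Graph, normalized: bool = False, snapshot_id: str = ""
) -> CentralityTable:
    """Compute all six features; one row per node, columns bc..nc.

    An edgeless graph gets EC = 0 for every node (the measure is undefined
    without edges, and nodes without edges carry no eigenvector mass).
    """
    if g.number_of_nodes() == 0:
        raise ValidationError("cannot compute centralities of an empty graph")
    nodes = sorted(g.nodes)
    if g.number_of_edges() > 0:
        ec = eigenvector_centrality(g)
    else:
        ec = dict.fromkeys(nodes, 0.0)
    data = {
        "bc": betweenness_centrality(g),
        "cc": closeness_centrality(g),
        "dc": degree_centrality(g),
        "ec": ec,
        "lac": local_average_connectivity(g),
        "nc": network_centrality(g),
    }
    frame = pd.DataFrame({f: [data[f][v] for v in nodes] for f in FEATURES},
                         index=pd.Index(nodes, name="node"))
    if normalized:
        n = len(nodes)
        if n > 2:
            frame["bc"] = frame["bc"] / ((n - 1) * (n - 2) / 2.0)
        if n > 1:
            frame["dc"] = frame["dc"] / (n - 1)
    return CentralityTable(frame=frame, snapshot_id=snapshot_id)
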