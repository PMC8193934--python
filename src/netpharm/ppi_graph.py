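"""Protein-protein-interaction graph construction.

The analysis graph is a simple undirected :class:`networkx.Graph` over gene
symbols, induced on the putative target set, with association confidence
kept as an edge attribute. Following the convention of confidence-filtered
interactome analyses, nodes left without any edge ("disconnected nodes") are
removed before analysis.
"""

from __future__ import annotations

import logging

import networkx as nx

from .errors import EmptyResultError
from .geneset_ops import GeneSet
from .io_formats import WeightedEdgeList

logger = logging.getLogger(__name__)


def build_ppi(
    edges: WeightedEdgeList, restrict_to: GeneSet | None = None
) -> nx.Graph:
    """Build the induced, isolated-node-free analysis graph.

    ``edges`` must already be confidence-thresholded by the reader. When
    ``restrict_to`` is given, only edges with both endpoints inside it
    survive (the induced subgraph on the putative targets); restricted genes
    that end up with no edge are never added.
    """
    allowed = restrict_to.symbols if restrict_to is not None else None
    g = nx.Graph()
    n_rejected = 0
    for a, b, score in edges.unit_scores():
        if allowed is not None and (a not in allowed or b not in allowed):
            n_rejected += 1
            continue
        g.add_edge(a, b, confidence=float(score))
    if g.number_of_nodes() == 0:
        raise EmptyResultError(
            "PPI graph is empty after restriction; nothing to analyse"
        )
    if allowed is not None:
        n_isolated = len(allowed) - g.number_of_nodes()
        logger.info(
            "build_ppi: %d/%d edges kept, %d restricted genes without edges",
            g.number_of_edges(), len(edges), n_isolated,
        )
    return g


def connected_components(g: nx.Graph) -> list[frozenset[str]]:
    """Partition of the node set by reachability, largest component first."""
    comps = [frozenset(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))
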