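"""Iterative above-median multi-feature hub extraction.

One round computes the six centrality features on the current graph, takes
the per-feature median over the current nodes (even counts use the midpoint
of the two central order statistics), and retains exactly the nodes that
*strictly* exceed all six medians. The induced subgraph on the retained
nodes, with any newly isolated nodes removed, feeds the next round. Because
strictly exceeding a median is possible for at most ``ceil((n - 1) / 2)``
nodes per feature, each round at least halves the graph (up to rounding).

Two rounds are the default; the filter stops early if a round would empty
the graph, returning the last non-empty node set, so the pipeline always
ends with a usable hub set (fully symmetric graphs, where no node exceeds
the median of a constant feature, trigger this immediately).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import networkx as nx

from .centrality import FEATURES, centrality_table
from .errors import ValidationError
from .geneset_ops import GeneSet

logger = logging.getLogger(__name__)

STOP_REASONS = ("completed", "would_empty", "converged")


@dataclass(frozen=True)
class FilterRoundReport:
    """Bookkeeping for one filter round."""

    round_index: int
    n_in: int
    medians: dict[str, float]
    retained: frozenset[str]
    n_isolated_dropped: int
    stop_reason: str = "completed"

    @property
    def n_out(self) -> int:
        return len(self.retained)


def median_filter_round(
    g: nx.Graph, round_index: int = 1, min_features: int = 6
) -> tuple[FilterRoundReport, nx.Graph]:
    """One strict-above-median filter round.

    ``min_features`` relaxes the conjunction: a node is retained when it
    strictly exceeds the median of at least that many of the six features
    (default 6, i.e. all of them). Nodes isolated by the deletion of their
    neighbors are dropped from the returned subgraph.
    """
    if not 1 <= min_features <= len(FEATURES):
        raise ValidationError(f"min_features must be in 1..6, got {min_features}")
    table = centrality_table(g, snapshot_id=f"round{round_index}")
    medians = table.medians()
    frame = table.frame
    exceed = sum((frame[f] > medians[f]).astype(int) for f in FEATURES)
    survivors = set(frame.index[exceed >= min_features])

    sub = g.subgraph(survivors).copy()
    isolated = [v for v in sub if sub.degree(v) == 0]
    sub.remove_nodes_from(isolated)
    report = FilterRoundReport(
        round_index=round_index,
        n_in=g.number_of_nodes(),
        medians=medians,
        retained=frozenset(sub.nodes),
        n_isolated_dropped=len(isolated),
    )
    logger.info(
        "round %d: %d -> %d nodes (%d isolated dropped); medians %s",
        round_index, report.n_in, report.n_out, len(isolated),
        {k: round(v, 4) for k, v in medians.items()},
    )
    return report, sub


def extract_hubs(
    g: nx.Graph, rounds: int = 2, min_features: int = 6
) -> tuple[GeneSet, list[FilterRoundReport]]:
    """Apply up to ``rounds`` median-filter rounds and return the hub set.

    Centralities are recomputed on the shrunken graph at each round. If a
    round would leave nothing, iteration stops and the previous round's node
    set is returned with stop reason ``would_empty``. ``rounds = 0`` is the
    identity (all nodes, no reports).
    """
    if g.number_of_nodes() == 0:
        raise ValidationError("cannot extract hubs from an empty graph")
    current = g
    reports: list[FilterRoundReport] = []
    for i in range(1, rounds + 1):
        report, nxt = median_filter_round(current, round_index=i,
                                          min_features=min_features)
        if nxt.number_of_nodes() == 0:
            reports.append(replace(report, stop_reason="would_empty"))
            break
        if set(nxt.nodes) == set(current.nodes):  # no further change possible
            reports.append(replace(report, stop_reason="converged"))
            current = nxt
            break
        reports.append(report)
        current = nxt
    hubs = GeneSet(name="hub_genes", symbols=frozenset(str(v) for v in current.nodes))
    logger.info("hub extraction finished with %d genes after %d round(s)",
                len(hubs), len(reports))
    return hubs, reports
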