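"""Herb-ingredient-target (HIT) tripartite network.

Nodes live in three partitions — herbs, ingredients (compounds), and target
genes — and edges only connect adjacent partitions: herb-ingredient
containment and ingredient-gene targeting. Node identifiers are namespaced
internally (``herb:``, ``mol:``, ``gene:``) so that a herb label can never
collide with a gene symbol; the bare label is kept as a node attribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .errors import EmptyResultError, ValidationError
from .geneset_ops import GeneSet
from .screening import ActiveComponentSet

logger = logging.getLogger(__name__)

PARTITIONS = ("herb", "ingredient", "gene")
_PREFIX = {"herb": "herb:", "ingredient": "mol:", "gene": "gene:"}


def _nid(partition: str, label: str) -> str:
    return _PREFIX[partition] + label


@dataclass(frozen=True)
class TripartiteNetwork:
    graph: nx.Graph

    def __post_init__(self) -> None:
        for node, data in self.graph.nodes(data=True):
            if data.get("partition") not in PARTITIONS:
                raise ValidationError(f"node {node} lacks a valid partition tag")
        for a, b in self.graph.edges():
            pa = self.graph.nodes[a]["partition"]
            pb = self.graph.nodes[b]["partition"]
            if {pa, pb} not in ({"herb", "ingredient"}, {"ingredient", "gene"}):
                raise ValidationError(
                    f"edge {a}--{b} connects non-adjacent partitions {pa}/{pb}"
                )
        for node, data in self.graph.nodes(data=True):
            if data["partition"] == "ingredient" and not any(
                self.graph.nodes[nbr]["partition"] == "herb"
                for nbr in self.graph[node]
            ):
                raise ValidationError(f"ingredient {node} is linked to no herb")

    def _labels(self, partition: str) -> frozenset[str]:
        return frozenset(
            data["label"]
            for _, data in self.graph.nodes(data=True)
            if data["partition"] == partition
        )

    @property
    def herbs(self) -> frozenset[str]:
        return self._labels("herb")

    @property
    def ingredients(self) -> frozenset[str]:
        return self._labels("ingredient")

    @property
    def genes(self) -> frozenset[str]:
        return self._labels("gene")

    def gene_degree(self, molecule_id: str) -> int:
        """Number of gene nodes adjacent to an ingredient node."""
        nid = _nid("ingredient", molecule_id)
        return sum(
            1 for nbr in self.graph[nid]
            if self.graph.nodes[nbr]["partition"] == "gene"
        )


def build_hit(
    active: ActiveComponentSet, putative_targets: GeneSet
) -> TripartiteNetwork:
    """Build the tripartite network restricted to the putative target genes.

    Ingredient-gene edges are kept only for genes inside ``putative_targets``;
    ingredients left without a single restricted target are dropped entirely.
    An ingredient shared by several herbs appears as one node linked to each
    containing herb.
    """
    if not putative_targets.symbols:
        raise ValidationError("putative target set is empty")
    g = nx.Graph()
    allowed = putative_targets.symbols

    # molecule -> restricted targets, merged across herbs (shared components)
    mol_targets: dict[str, set[str]] = {}
    mol_herbs: dict[str, set[str]] = {}
    for herb, mols in active.targets_by_herb.items():
        for mol, genes in mols.items():
            mol_targets.setdefault(mol, set()).update(genes & allowed)
            mol_herbs.setdefault(mol, set()).add(herb)

    n_dropped = 0
    for mol, genes in sorted(mol_targets.items()):
        if not genes:
            n_dropped += 1
            continue
        mid = _nid("ingredient", mol)
        g.add_node(mid, partition="ingredient", label=mol)
        for herb in sorted(mol_herbs[mol]):
            hid = _nid("herb", herb)
            g.add_node(hid, partition="herb", label=herb)
            g.add_edge(hid, mid, interaction="contains")
        for gene in sorted(genes):
            gid = _nid("gene", gene)
            g.add_node(gid, partition="gene", label=gene)
            g.add_edge(mid, gid, interaction="targets")

    if g.number_of_nodes() == 0:
        raise EmptyResultError(
            "no ingredient targets any putative gene; HIT network is empty"
        )
    if n_dropped:
        logger.info("dropped %d ingredients with no restricted target", n_dropped)
    return TripartiteNetwork(graph=g)


def per_herb_target_partition(net: TripartiteNetwork) -> dict[str, frozenset[str]]:
    """For each herb, the union of genes reachable through its ingredients.

    Herbs may overlap (shared components), so the sum of per-herb set sizes
    can exceed the size of their union.
    """
    g = net.graph
    out: dict[str, set[str]] = {}
    for node, data in g.nodes(data=True):
        if data["partition"] != "herb":
            continue
        genes: set[str] = set()
        for mol in g[node]:
            for nbr in g[mol]:
                if g.nodes[nbr]["partition"] == "gene":
                    genes.add(g.nodes[nbr]["label"])
        out[data["label"]] = genes
    return {h: frozenset(s) for h, s in out.items()}


def representative_components(
    net: TripartiteNetwork, hub_genes: GeneSet
) -> dict[str, str]:
    """Pick one representative compound per herb by hub-gene degree.

    The network is first restricted to gene nodes in ``hub_genes`` (compounds
    with no hub target drop out). For each herb the compound with maximal
    gene-degree is selected; ties break to the lexicographically smallest
    molecule id and are logged. Herbs with no qualifying compound are omitted
    with a warning.
    """
    g = net.graph
    allowed = {_nid("gene", s) for s in hub_genes.symbols}

    # restricted gene-degree per ingredient
    restricted_degree: dict[str, int] = {}
    for node, data in g.nodes(data=True):
        if data["partition"] != "ingredient":
            continue
        deg = sum(
            1 for nbr in g[node]
            if g.nodes[nbr]["partition"] == "gene" and nbr in allowed
        )
        restricted_degree[node] = deg

    chosen: dict[str, str] = {}
    for node, data in sorted(g.nodes(data=True)):
        if data["partition"] != "herb":
            continue
        herb = data["label"]
        candidates = [
            (g.nodes[mol]["label"], restricted_degree[mol])
            for mol in g[node]
            if restricted_degree.get(mol, 0) > 0
        ]
        if not candidates:
            logger.warning("herb %s: no ingredient touches a hub gene; omitted", herb)
            continue
        best_degree = max(d for _, d in candidates)
        tied = sorted(label for label, d in candidates if d == best_degree)
        if len(tied) > 1:
            logger.warning(
                "herb %s: degree tie among %s; choosing %s", herb, tied, tied[0]
            )
        chosen[herb] = tied[0]
    return chosen
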