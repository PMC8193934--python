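"""Set algebra over named gene sets.

Gene symbols are plain uppercase strings compared for exact equality; alias
resolution happens upstream (the symbol map applied during target mapping).
A :class:`GeneSet` carries provenance so that multi-source merges remember,
per symbol, which source lists contributed it — this is what lets the Venn
partition be recomputed from the merged object alone.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from .errors import EmptyResultError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    """A named, deduplicated set of uppercase gene symbols.

    Parameters
    ----------
    name:
        Label for the set (e.g. a database name or ``"putative_targets"``).
    symbols:
        The member gene symbols. Uppercased on construction.
    sources:
        Labels of the source lists this set was built from.
    provenance:
        Optional per-symbol mapping to the subset of ``sources`` that
        contributed the symbol. Populated by :func:`merge_sources`.
    """

    name: str
    symbols: frozenset[str]
    sources: tuple[str, ...] = ()
    provenance: Mapping[str, frozenset[str]] | None = field(
        default=None, compare=False
    )

    def __post_init__(self) -> None:
        upper = frozenset(s.upper() for s in self.symbols)
        object.__setattr__(self, "symbols", upper)

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.symbols

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.symbols))


@dataclass(frozen=True)
class VennPartition:
    """Disjoint region decomposition of 2-6 gene sets.

    ``regions`` maps each non-empty combination of set labels (as a frozenset)
    to the tuple of symbols belonging to exactly those sets. Regions are
    disjoint by construction and their counts sum to the union size.
    """

    labels: tuple[str, ...]
    regions: Mapping[frozenset[str], tuple[str, ...]]

    @property
    def counts(self) -> dict[frozenset[str], int]:
        return {region: len(members) for region, members in self.regions.items()}

    @property
    def union_size(self) -> int:
        return sum(len(members) for members in self.regions.values())

    def count(self, *labels: str) -> int:
        """Number of symbols in exactly the region defined by ``labels``."""
        return len(self.regions.get(frozenset(labels), ()))


def merge_sources(sets: Iterable[GeneSet], name: str = "merged") -> GeneSet:
    """Union several gene sets, deleting redundant symbols.

    Each symbol in the result remembers the labels of every input set that
    contained it (the merge provenance).
    """
    sets = list(sets)
    if not sets:
        raise ValidationError("merge_sources requires at least one gene set")
    provenance: dict[str, set[str]] = {}
    sources: list[str] = []
    for gs in sets:
        label = gs.name
        sources.append(label)
        for symbol in gs.symbols:
            provenance.setdefault(symbol, set()).add(label)
    return GeneSet(
        name=name,
        symbols=frozenset(provenance),
        sources=tuple(sources),
        provenance={s: frozenset(v) for s, v in provenance.items()},
    )


def venn_partition(sets: Iterable[GeneSet]) -> VennPartition:
    """Exhaustive, disjoint region counts for 2-6 gene sets.

    Every symbol of the union is assigned to exactly one region: the set of
    labels of the inputs that contain it. All ``2^k - 1`` regions are
    reported, including empty ones.
    """
    sets = list(sets)
    if not 2 <= len(sets) <= 6:
        raise ValidationError(
            f"venn_partition supports 2-6 sets, got {len(sets)}"
        )
    labels = [gs.name for gs in sets]
    if len(set(labels)) != len(labels):
        raise ValidationError("gene set names must be unique for Venn analysis")

    membership: dict[str, set[str]] = {}
    for gs in sets:
        for symbol in gs.symbols:
            membership.setdefault(symbol, set()).add(gs.name)

    regions: dict[frozenset[str], list[str]] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            regions[frozenset(combo)] = []
    for symbol, labs in membership.items():
        regions[frozenset(labs)].append(symbol)

    return VennPartition(
        labels=tuple(labels),
        regions={k: tuple(sorted(v)) for k, v in regions.items()},
    )


def intersect_drug_disease(
    drug_targets: GeneSet, disease: GeneSet, name: str = "putative_targets"
) -> GeneSet:
    """Intersect drug target genes with disease genes.

    The result is the set of putative therapeutic targets. An empty
    intersection stops the pipeline: downstream network construction has no
    nodes to work with.
    """
    if not drug_targets.symbols or not disease.symbols:
        raise ValidationError("both gene sets must be non-empty")
    shared = drug_targets.symbols & disease.symbols
    if not shared:
        raise EmptyResultError(
            f"no overlap between '{drug_targets.name}' and '{disease.name}'"
        )
    logger.info(
        "intersected %s (%d) with %s (%d): %d shared symbols",
        drug_targets.name,
        len(drug_targets),
        disease.name,
        len(disease),
        len(shared),
    )
    return GeneSet(
        name=name,
        symbols=frozenset(shared),
        sources=(drug_targets.name, disease.name),
    )
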