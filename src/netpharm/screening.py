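"""Active-ingredient screening and target mapping.

Candidate herbal compounds are screened on two TCMSP-style pharmacokinetic
criteria: oral bioavailability (OB, percent) and drug-likeness (DL, unitless
0-1). Both thresholds are inclusive — a compound at exactly OB = 20 and
DL = 0.1 passes. Surviving compounds are then mapped to the human gene
symbols of their protein targets via a table-driven symbol map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

from .errors import EmptyResultError
from .geneset_ops import GeneSet
from .io_formats import IngredientTable, TargetMapTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ActiveComponentSet:
    """Screened compounds with their per-herb target gene sets.

    ``targets_by_herb`` maps herb -> molecule -> frozenset of gene symbols.
    Molecules with zero mapped targets stay in the mapping (empty set) and
    are listed in ``flagged_molecules``.
    """

    targets_by_herb: Mapping[str, Mapping[str, frozenset[str]]]
    flagged_molecules: frozenset[str] = frozenset()
    n_unmapped_names: int = 0

    @property
    def n_ingredients(self) -> int:
        return sum(len(mols) for mols in self.targets_by_herb.values())

    @property
    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for mols in self.targets_by_herb.values():
            for genes in mols.values():
                out |= genes
        return frozenset(out)

    def per_herb_union(self) -> dict[str, frozenset[str]]:
        return {
            herb: frozenset().union(*mols.values()) if mols else frozenset()
            for herb, mols in self.targets_by_herb.items()
        }

    def union_geneset(self, name: str = "drug_targets") -> GeneSet:
        return GeneSet(name=name, symbols=self.union)


def screen_ingredients(
    table: IngredientTable, ob_min: float = 20.0, dl_min: float = 0.1
) -> IngredientTable:
    """Retain compounds with OB >= ob_min and DL >= dl_min (both inclusive).

    Row order is preserved, so screening an already-screened table is the
    identity. Kept/dropped counts per herb are logged.
    """
    kept = tuple(
        rec for rec in table.rows if rec.ob >= ob_min and rec.dl >= dl_min
    )
    per_herb: dict[str, list[int]] = {}
    for rec in table.rows:
        counts = per_herb.setdefault(rec.herb_id, [0, 0])
        passed = rec.ob >= ob_min and rec.dl >= dl_min
        counts[0 if passed else 1] += 1
    for herb in sorted(per_herb):
        k, d = per_herb[herb]
        logger.info("screen %s: kept %d, dropped %d (OB>=%g, DL>=%g)",
                    herb, k, d, ob_min, dl_min)
    return IngredientTable(rows=kept)


def map_targets(
    active: IngredientTable,
    targets: TargetMapTable,
    symbol_map: Mapping[str, str] | None = None,
) -> ActiveComponentSet:
    """Map screened compounds to deduplicated gene-symbol sets per herb.

    A target row contributes its ``gene_symbol`` if present, otherwise the
    ``symbol_map`` translation of its ``target_name``. Target names that map
    to nothing are dropped and counted. Molecules without a single mapped
    target are kept in the component listing but flagged.
    """
    symbol_map = symbol_map or {}
    by_molecule = targets.by_molecule()
    result: dict[str, dict[str, frozenset[str]]] = {}
    flagged: set[str] = set()
    n_unmapped = 0

    for rec in active.rows:
        genes: set[str] = set()
        for trow in by_molecule.get(rec.molecule_id, ()):
            symbol = trow.gene_symbol or symbol_map.get(trow.target_name, "")
            if symbol:
                genes.add(symbol.upper())
            else:
                n_unmapped += 1
        result.setdefault(rec.herb_id, {})[rec.molecule_id] = frozenset(genes)
        if not genes:
            flagged.add(rec.molecule_id)

    if n_unmapped:
        logger.warning("dropped %d target names without a gene symbol", n_unmapped)
    if flagged:
        logger.warning("%d molecules have no mapped targets", len(flagged))

    acs = ActiveComponentSet(
        targets_by_herb={h: dict(m) for h, m in result.items()},
        flagged_molecules=frozenset(flagged),
        n_unmapped_names=n_unmapped,
    )
    if not acs.union:
        raise EmptyResultError("no compound maps to any gene symbol")
    return acs
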