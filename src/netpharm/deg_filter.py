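"""Differential-expression calls from a precomputed DE table.

The classifier applies strict thresholds on both axes: a gene is called
up-regulated when ``padj < padj_max`` and ``log2fc > lfc_min``, and
down-regulated when ``padj < padj_max`` and ``log2fc < -lfc_min``. Boundary
rows (``log2fc`` exactly at the threshold, or ``padj`` exactly at the cap)
are classed unchanged. The upstream differential test itself is not part of
this package; any table with gene/log2fc/pvalue/padj columns is accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .geneset_ops import GeneSet
from .io_formats import DETable

logger = logging.getLogger(__name__)

CLASSES = ("up", "down", "unchanged")


@dataclass(frozen=True)
class DEGCall:
    gene_symbol: str
    klass: str
    log2fc: float
    padj: float


@dataclass(frozen=True)
class DEGSummary:
    n_up: int
    n_down: int

    @property
    def n_de(self) -> int:
        return self.n_up + self.n_down


def call_degs(
    table: DETable, padj_max: float = 0.05, lfc_min: float = 1.0
) -> tuple[list[DEGCall], DEGSummary]:
    """Classify every row as up / down / unchanged (strict thresholds)."""
    calls: list[DEGCall] = []
    n_up = n_down = 0
    for row in table.frame.itertuples(index=False):
        lfc = float(row.log2fc)
        padj = float(row.padj)
        if padj < padj_max and lfc > lfc_min:
            klass = "up"
            n_up += 1
        elif padj < padj_max and lfc < -lfc_min:
            klass = "down"
            n_down += 1
        else:
            klass = "unchanged"
        calls.append(DEGCall(gene_symbol=row.gene, klass=klass,
                             log2fc=lfc, padj=padj))
    summary = DEGSummary(n_up=n_up, n_down=n_down)
    logger.info("DEG calling: %d up, %d down, %d total DE of %d genes",
                summary.n_up, summary.n_down, summary.n_de, len(calls))
    return calls, summary


def deg_geneset(calls: list[DEGCall], direction: str) -> GeneSet:
    """Extract the up- or down-regulated gene set for downstream reuse."""
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    symbols = frozenset(c.gene_symbol for c in calls if c.klass == direction)
    if not symbols:
        logger.warning("no %s-regulated genes at the current thresholds", direction)
    return GeneSet(name=f"{direction}_regulated", symbols=symbols)
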