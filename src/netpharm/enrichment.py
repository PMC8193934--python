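"""Over-representation analysis (ORA) with Benjamini-Hochberg correction.

Each annotation term is tested with the one-sided hypergeometric
upper-tail probability (equivalently the one-tailed Fisher exact test):
given a universe of ``N`` genes of which ``K`` carry the term, the chance
that a random query of size ``n`` overlaps the term in ``k`` or more genes.
P-values are adjusted per namespace (BP/CC/MF/KEGG) by default, mirroring
how GO panels are usually reported; a pooled mode adjusts across all
namespaces at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptyResultError, ValidationError
from .geneset_ops import GeneSet
from .io_formats import AnnotationSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    term_name: str
    namespace: str
    k: int  # query genes carrying the term
    K: int  # term size within the universe
    n: int  # query size within the universe
    N: int  # universe size
    p: float
    padj: float
    significant: bool


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    Evaluated through the survival function of the hypergeometric
    distribution, which works in log space internally and is stable for
    large universes.
    """
    for name, value in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(value) != value or value < 0:
            raise ValidationError(f"{name} must be a non-negative integer")
    if K > N or n > N:
        raise ValidationError(f"inconsistent arguments: K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, capped at 1, order-preserving."""
    arr = np.asarray(list(pvalues), dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or not np.all(np.isfinite(arr)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1].tolist()


def enrich(
    query: GeneSet,
    annotations: AnnotationSet,
    universe: GeneSet | None = None,
    alpha: float = 0.05,
    per_namespace: bool = True,
) -> list[EnrichmentRow]:
    """Test every annotation term for over-representation in ``query``.

    The universe defaults to all genes appearing in the annotation set;
    query and terms are intersected with it first, and terms without any
    universe member are skipped. Rows are BH-adjusted (per namespace unless
    ``per_namespace=False``), flagged significant when ``padj < alpha``
    (strict), and sorted by (padj, p, term_id).
    """
    background = (
        universe.symbols if universe is not None else annotations.all_genes
    )
    if not background:
        raise ValidationError("enrichment universe is empty")
    q = query.symbols & background
    if not q:
        raise EmptyResultError(
            "query has no overlap with the enrichment universe"
        )
    dropped = len(query.symbols) - len(q)
    if dropped:
        logger.info("enrich: %d query genes outside the universe ignored", dropped)

    n = len(q)
    big_n = len(background)
    raw: list[tuple[str, str, str, int, int, float]] = []
    for term in sorted(annotations, key=lambda t: t.term_id):
        members = term.members & background
        if not members:
            continue
        k = len(q & members)
        p = hypergeom_upper_tail(k, len(members), n, big_n)
        raw.append((term.term_id, term.term_name, term.namespace,
                    k, len(members), p))

    rows: list[EnrichmentRow] = []
    groups: dict[str, list[int]] = {}
    for idx, rec in enumerate(raw):
        key = rec[2] if per_namespace else "all"
        groups.setdefault(key, []).append(idx)
    padj = [0.0] * len(raw)
    for indices in groups.values():
        adjusted = bh_adjust([raw[i][5] for i in indices])
        for i, a in zip(indices, adjusted):
            padj[i] = a
    for (term_id, term_name, namespace, k, big_k, p), a in zip(raw, padj):
        rows.append(EnrichmentRow(
            term_id=term_id, term_name=term_name, namespace=namespace,
            k=k, K=big_k, n=n, N=big_n, p=p, padj=a,
            significant=a < alpha,
        ))
    rows.sort(key=lambda r: (r.padj, r.p, r.term_id))
    return rows
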