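"""Synthetic pipeline inputs with known ground truth.

Every generator is a pure function of its parameters and a seed, and returns
alongside its output a *ledger* recording the planted structure (which
ingredients pass the screen, the disease-gene union, the dense PPI module,
the enriched annotation term, the up/down DE counts). The ledger fully
determines the expected output of every deterministic pipeline stage on the
generated instance, which is what makes end-to-end testing possible without
any database download.

Distributions are deliberately plain — uniform values, Bernoulli edges — the
pipeline's logic is under test, not the marginal statistics of TCMSP or
STRING. Default sizes keep the whole instance at interactome-subnetwork
scale (a 200-node PPI graph with a 30-node planted module) so a full run
takes seconds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geneset_ops import GeneSet
from .io_formats import (
    AnnotationSet,
    AnnotationTerm,
    DETable,
    IngredientRecord,
    IngredientTable,
    TargetMapTable,
    TargetRecord,
    WeightedEdgeList,
    write_de_table,
    write_gene_list,
    write_gmt,
    write_ingredient_table,
    write_symbol_map,
    write_target_map,
    write_weighted_edges,
)

import pandas as pd

DISEASE_SOURCES = ("genecards", "drugbank", "omim", "pharmgkb", "ttd")


# ---------------------------------------------------------------------------
# Ledgers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IngredientLedger:
    seed: int
    n_rows: int
    n_pass: int
    pass_keys: tuple[tuple[str, str], ...]  # (herb_id, molecule_id)


@dataclass(frozen=True)
class TargetMapLedger:
    seed: int
    drug_union: tuple[str, ...]
    per_herb_union: dict[str, tuple[str, ...]]
    n_unmapped_rows: int


@dataclass(frozen=True)
class DiseaseLedger:
    seed: int
    union: tuple[str, ...]
    union_size: int
    per_source_sizes: dict[str, int]
    pairwise_overlaps: dict[str, int]


@dataclass(frozen=True)
class PPILedger:
    seed: int
    module_nodes: tuple[str, ...]
    n_nodes: int
    n_connected_nodes: int
    n_edges: int  # confidence >= 0.7 rows
    n_module_edges: int
    n_background_edges: int
    n_cross_edges: int
    n_decoy_rows: int  # sub-threshold rows, dropped by the reader


@dataclass(frozen=True)
class AnnotationLedger:
    seed: int
    n_terms: int
    planted_term_id: str | None
    planted_overlap: int


@dataclass(frozen=True)
class DELedger:
    seed: int
    n_genes: int
    n_up: int
    n_down: int


@dataclass(frozen=True)
class GeneratorLedger:
    """Composite ground truth for one simulated pipeline instance."""

    seed: int
    ingredients: IngredientLedger
    targets: TargetMapLedger
    disease: DiseaseLedger
    intersection: tuple[str, ...]
    ppi: PPILedger
    annotations: AnnotationLedger
    de: DELedger

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True,
                      default=list)


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


# ---------------------------------------------------------------------------
# Ingredient tables
# ---------------------------------------------------------------------------

def gen_ingredients(
    n_herbs: int = 10,
    n_per_herb: int = 20,
    frac_pass: float = 0.4,
    seed: int = 0,
) -> tuple[IngredientTable, IngredientLedger]:
    """Generate OB/DL values with an exact planted pass set.

    Passers draw OB ~ U(20, 60) and DL ~ U(0.1, 0.6); the first passer is
    pinned to the exact (OB = 20, DL = 0.1) boundary so the inclusive
    threshold is always exercised. Failers violate at least one bound.
    """
    if not 0.0 < frac_pass < 1.0:
        raise ValueError("frac_pass must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_total = n_herbs * n_per_herb
    n_pass = round(frac_pass * n_total)
    pass_idx = set(rng.choice(n_total, size=n_pass, replace=False).tolist())
    first_pass = min(pass_idx) if pass_idx else None

    rows: list[IngredientRecord] = []
    pass_keys: list[tuple[str, str]] = []
    idx = 0
    for h in range(1, n_herbs + 1):
        herb = f"HB{h:02d}"
        for _ in range(n_per_herb):
            mol = f"MOL{idx + 1:04d}"
            if idx in pass_idx:
                if idx == first_pass:
                    ob, dl = 20.0, 0.1
                else:
                    ob = 20.0 + 40.0 * rng.random()
                    dl = 0.1 + 0.5 * rng.random()
                pass_keys.append((herb, mol))
            else:
                mode = int(rng.integers(0, 3))
                low_ob = 19.9 * rng.random()
                low_dl = 0.099 * rng.random()
                if mode == 0:
                    ob, dl = low_ob, 0.1 + 0.5 * rng.random()
                elif mode == 1:
                    ob, dl = 20.0 + 40.0 * rng.random(), low_dl
                else:
                    ob, dl = low_ob, low_dl
            rows.append(IngredientRecord(
                herb_id=herb, molecule_id=mol,
                molecule_name=f"compound_{idx + 1}", ob=ob, dl=dl,
            ))
            idx += 1
    table = IngredientTable(rows=tuple(rows))
    ledger = IngredientLedger(
        seed=seed, n_rows=n_total, n_pass=n_pass, pass_keys=tuple(pass_keys)
    )
    return table, ledger


# ---------------------------------------------------------------------------
# Target maps
# ---------------------------------------------------------------------------

def gen_target_map(
    ingredients: IngredientTable,
    pass_keys: tuple[tuple[str, str], ...],
    drug_union_size: int = 300,
    targets_per_molecule: tuple[int, int] = (3, 30),
    n_unmapped_rows: int = 10,
    seed: int = 0,
) -> tuple[TargetMapTable, dict[str, str], TargetMapLedger]:
    """Assign gene targets to molecules so screened compounds cover a known
    union.

    Every gene of the drug union is guaranteed at least one screened
    (passing) molecule, so the mapped target union equals the ledger's. The
    protein names go through a generated name -> symbol map, with
    ``n_unmapped_rows`` extra rows whose names have no mapping (they must be
    dropped, with a count, downstream).
    """
    rng = np.random.default_rng(seed)
    union = [f"TG{i:04d}" for i in range(1, drug_union_size + 1)]
    pass_set = set(pass_keys)
    lo, hi = targets_per_molecule

    assignment: dict[str, list[str]] = {}
    herb_of: dict[str, str] = {}
    for rec in ingredients.rows:
        herb_of[rec.molecule_id] = rec.herb_id
        k = int(rng.integers(lo, hi + 1))
        assignment[rec.molecule_id] = rng.choice(
            union, size=min(k, len(union)), replace=False
        ).tolist()

    passing_mols = sorted(m for (_, m) in pass_set)
    covered: set[str] = set()
    for mol in passing_mols:
        covered.update(assignment[mol])
    for gene in union:
        if gene not in covered:
            mol = passing_mols[int(rng.integers(0, len(passing_mols)))]
            assignment[mol].append(gene)

    rows: list[TargetRecord] = []
    symbol_map: dict[str, str] = {}
    for mol in sorted(assignment):
        for gene in sorted(set(assignment[mol])):
            name = f"prot_{gene}"
            symbol_map[name] = gene
            rows.append(TargetRecord(mol, name, ""))
    for i in range(n_unmapped_rows):
        mol = passing_mols[int(rng.integers(0, len(passing_mols)))]
        rows.append(TargetRecord(mol, f"prot_unknown_{i + 1}", ""))

    per_herb: dict[str, set[str]] = {}
    for herb, mol in pass_set:
        per_herb.setdefault(herb, set()).update(assignment[mol])
    ledger = TargetMapLedger(
        seed=seed,
        drug_union=tuple(sorted(union)),
        per_herb_union={h: tuple(sorted(s)) for h, s in sorted(per_herb.items())},
        n_unmapped_rows=n_unmapped_rows,
    )
    return TargetMapTable(rows=tuple(rows)), symbol_map, ledger


# ---------------------------------------------------------------------------
# Disease sources
# ---------------------------------------------------------------------------

def gen_disease_sources(
    n_sources: int = 5,
    union_size: int = 500,
    redundancy: float = 1.6,
    seed: int = 0,
    gene_names: list[str] | None = None,
    source_names: tuple[str, ...] | None = None,
) -> tuple[list[GeneSet], DiseaseLedger]:
    """Multi-source disease gene lists with controlled redundancy.

    Each union gene is assigned to at least one source; the expected number
    of sources per gene equals ``redundancy``. The ledger records the union,
    per-source sizes, and pairwise overlaps.
    """
    if n_sources < 1:
        raise ValueError("need at least one source")
    if not 1.0 <= redundancy <= n_sources:
        raise ValueError(f"redundancy must be in [1, {n_sources}]")
    rng = np.random.default_rng(seed)
    names = source_names or tuple(
        DISEASE_SOURCES[i] if i < len(DISEASE_SOURCES) else f"source{i + 1}"
        for i in range(n_sources)
    )
    genes = gene_names or [f"DG{i:04d}" for i in range(1, union_size + 1)]
    if len(genes) != union_size:
        raise ValueError("gene_names length must equal union_size")

    members: dict[str, set[str]] = {name: set() for name in names}
    p_extra = (redundancy - 1.0) / max(n_sources - 1, 1)
    for gene in genes:
        n_assign = 1 + int(rng.binomial(n_sources - 1, p_extra)) if n_sources > 1 else 1
        chosen = rng.choice(n_sources, size=n_assign, replace=False)
        for c in chosen:
            members[names[int(c)]].add(gene.upper())

    sets = [
        GeneSet(name=name, symbols=frozenset(members[name]), sources=(name,))
        for name in names
    ]
    overlaps = {
        f"{a}&{b}": len(members[a] & members[b])
        for i, a in enumerate(names)
        for b in names[i + 1:]
    }
    ledger = DiseaseLedger(
        seed=seed,
        union=tuple(sorted(g.upper() for g in genes)),
        union_size=union_size,
        per_source_sizes={name: len(members[name]) for name in names},
        pairwise_overlaps=overlaps,
    )
    return sets, ledger


# ---------------------------------------------------------------------------
# PPI edge lists with a planted dense module
# ---------------------------------------------------------------------------

def gen_ppi(
    n_background: int = 170,
    module_size: int = 30,
    p_module: float = 0.8,
    p_background: float = 0.05,
    p_cross: float = 0.02,
    seed: int = 0,
    node_names: list[str] | None = None,
    n_decoy_rows: int = 0,
) -> tuple[WeightedEdgeList, PPILedger]:
    """STRING-style edge list with a planted dense module.

    The first ``module_size`` node names form the module; pairs inside it
    are wired with probability ``p_module``, background pairs with
    ``p_background``, and module-background pairs with ``p_cross``. Emitted
    association edges carry unit-interval confidences >= 0.7. Optional decoy
    rows carry sub-threshold confidences and must be removed by the
    thresholding reader.
    """
    rng = np.random.default_rng(seed)
    n_nodes = module_size + n_background
    names = node_names or [f"P{i:04d}" for i in range(1, n_nodes + 1)]
    if len(names) != n_nodes:
        raise ValueError("node_names length must equal module_size + n_background")
    names = [n.upper() for n in names]
    module = names[:module_size]
    module_set = set(module)

    edges: list[tuple[str, str, float]] = []
    counts = {"module": 0, "background": 0, "cross": 0}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            a, b = names[i], names[j]
            in_a, in_b = a in module_set, b in module_set
            if in_a and in_b:
                p, kind = p_module, "module"
            elif not in_a and not in_b:
                p, kind = p_background, "background"
            else:
                p, kind = p_cross, "cross"
            if rng.random() < p:
                score = 0.7 + 0.299 * rng.random()
                edges.append((min(a, b), max(a, b), round(score, 3)))
                counts[kind] += 1

    present = {(a, b) for a, b, _ in edges}
    decoys: list[tuple[str, str, float]] = []
    while len(decoys) < n_decoy_rows:
        i, j = rng.integers(0, n_nodes, size=2)
        if i == j:
            continue
        a, b = sorted((names[int(i)], names[int(j)]))
        if (a, b) in present:
            continue
        present.add((a, b))
        decoys.append((a, b, round(0.2 + 0.49 * rng.random(), 3)))

    connected = {a for a, _, _ in edges} | {b for _, b, _ in edges}
    ledger = PPILedger(
        seed=seed,
        module_nodes=tuple(sorted(module)),
        n_nodes=n_nodes,
        n_connected_nodes=len(connected),
        n_edges=len(edges),
        n_module_edges=counts["module"],
        n_background_edges=counts["background"],
        n_cross_edges=counts["cross"],
        n_decoy_rows=len(decoys),
    )
    all_rows = tuple(sorted(edges + decoys))
    return WeightedEdgeList(edges=all_rows, score_scale="unit"), ledger


# ---------------------------------------------------------------------------
# Annotations and DE tables
# ---------------------------------------------------------------------------

def gen_annotations(
    query: list[str],
    universe: list[str],
    n_terms: int = 50,
    term_size_range: tuple[int, int] = (10, 40),
    planted_term_overlap: float = 0.8,
    seed: int = 0,
    namespace: str = "KEGG",
    plant: bool = True,
) -> tuple[AnnotationSet, AnnotationLedger]:
    """Null annotation terms plus (optionally) one term planted to overlap
    the designated query heavily."""
    rng = np.random.default_rng(seed)
    universe = sorted({u.upper() for u in universe})
    query = sorted({q.upper() for q in query})
    lo, hi = term_size_range
    terms: dict[str, AnnotationTerm] = {}
    for t in range(1, n_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=min(size, len(universe)),
                             replace=False)
        term_id = f"T{t:04d}"
        terms[term_id] = AnnotationTerm(
            term_id, f"null term {t}", namespace, frozenset(members.tolist())
        )

    planted_id: str | None = None
    overlap = 0
    if plant:
        size = (lo + hi) // 2
        overlap = min(len(query), max(1, round(planted_term_overlap * size)))
        inside = rng.choice(query, size=overlap, replace=False).tolist()
        rest_pool = [u for u in universe if u not in set(query)]
        n_rest = min(size - overlap, len(rest_pool))
        rest = rng.choice(rest_pool, size=n_rest, replace=False).tolist() \
            if n_rest > 0 else []
        planted_id = "T_PLANTED"
        terms[planted_id] = AnnotationTerm(
            planted_id, "planted enriched term", namespace,
            frozenset(inside + rest),
        )
    ledger = AnnotationLedger(
        seed=seed, n_terms=len(terms),
        planted_term_id=planted_id, planted_overlap=overlap,
    )
    return AnnotationSet(terms=terms), ledger


def gen_de_table(
    n_genes: int = 15000,
    n_up: int = 141,
    n_down: int = 643,
    seed: int = 0,
) -> tuple[DETable, DELedger]:
    """DE table with exactly the planted up/down counts.

    Up rows have log2FC > 1 and padj < 0.05; down rows mirror them below
    -1; every other row violates at least one threshold (|log2FC| <= 1, or
    padj >= 0.05).
    """
    if n_up + n_down > n_genes:
        raise ValueError("n_up + n_down cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_genes)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    lfc = np.empty(n_genes)
    padj = np.empty(n_genes)

    up_idx = order[:n_up]
    down_idx = order[n_up:n_up + n_down]
    null_idx = order[n_up + n_down:]

    lfc[up_idx] = 1.01 + 4.0 * rng.random(n_up)
    lfc[down_idx] = -(1.01 + 4.0 * rng.random(n_down))
    padj[up_idx] = 1e-6 + 0.0489 * rng.random(n_up)
    padj[down_idx] = 1e-6 + 0.0489 * rng.random(n_down)

    n_null = len(null_idx)
    half = n_null // 2
    # small-effect nulls: |log2FC| <= 1, any padj
    lfc[null_idx[:half]] = -1.0 + 2.0 * rng.random(half)
    padj[null_idx[:half]] = rng.random(half)
    # non-significant nulls: large effect but padj >= 0.05
    signs = rng.choice([-1.0, 1.0], size=n_null - half)
    lfc[null_idx[half:]] = signs * (1.01 + 2.0 * rng.random(n_null - half))
    padj[null_idx[half:]] = 0.05 + 0.95 * rng.random(n_null - half)

    pvalue = padj * rng.random(n_genes)
    frame = pd.DataFrame({
        "gene": genes, "log2fc": lfc, "pvalue": pvalue, "padj": padj,
    })
    table = DETable(frame=frame)
    return table, DELedger(seed=seed, n_genes=n_genes, n_up=n_up, n_down=n_down)


# ---------------------------------------------------------------------------
# Composite instance ("paperlike" preset)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationBundle:
    ingredients: IngredientTable
    target_map: TargetMapTable
    symbol_map: dict[str, str]
    disease_sources: list[GeneSet]
    ppi_edges: WeightedEdgeList
    annotations: AnnotationSet
    de_table: DETable
    ledger: GeneratorLedger


def simulate(seed: int = 7, outdir: str | Path | None = None) -> SimulationBundle:
    """Generate a complete, internally consistent pipeline instance.

    The preset mirrors the scale of a decoction-vs-disease analysis: 10
    herbs with 20 candidate compounds each (40% passing the screen), a
    300-gene drug target union, a 500-gene five-source disease union
    sharing exactly 200 genes with the drug targets, a 200-node PPI graph
    over those shared genes with a 30-node planted dense module, 50
    annotation terms with one planted to overlap the module, and a DE table
    with 141 up- and 643 down-regulated genes among 15,000.

    When ``outdir`` is given, all input files plus ``ledger.json`` are
    written there in the formats the readers expect.
    """
    s = _child_seeds(seed, 7)
    ingredients, ing_ledger = gen_ingredients(
        n_herbs=10, n_per_herb=20, frac_pass=0.4, seed=s[0]
    )
    target_map, symbol_map, tgt_ledger = gen_target_map(
        ingredients, ing_ledger.pass_keys, drug_union_size=300, seed=s[1]
    )

    rng = np.random.default_rng(s[6])
    drug_union = list(tgt_ledger.drug_union)
    shared = sorted(
        rng.choice(drug_union, size=200, replace=False).tolist()
    )
    disease_only = [f"DG{i:04d}" for i in range(1, 301)]
    disease_names = shared + disease_only
    rng.shuffle(disease_names)
    disease_sources, dis_ledger = gen_disease_sources(
        n_sources=5, union_size=len(disease_names), redundancy=1.6,
        seed=s[2], gene_names=disease_names,
    )

    ppi_names = list(shared)
    rng.shuffle(ppi_names)
    ppi_edges, ppi_ledger = gen_ppi(
        n_background=170, module_size=30, seed=s[3],
        node_names=ppi_names, n_decoy_rows=100,
    )

    annotations, ann_ledger = gen_annotations(
        query=list(ppi_ledger.module_nodes), universe=shared,
        n_terms=50, seed=s[4],
    )
    de_table, de_ledger = gen_de_table(seed=s[5])

    ledger = GeneratorLedger(
        seed=seed, ingredients=ing_ledger, targets=tgt_ledger,
        disease=dis_ledger, intersection=tuple(shared),
        ppi=ppi_ledger, annotations=ann_ledger, de=de_ledger,
    )
    bundle = SimulationBundle(
        ingredients=ingredients, target_map=target_map, symbol_map=symbol_map,
        disease_sources=disease_sources, ppi_edges=ppi_edges,
        annotations=annotations, de_table=de_table, ledger=ledger,
    )
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle: SimulationBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_ingredient_table(bundle.ingredients, outdir / "ingredients.tsv")
    write_target_map(bundle.target_map, outdir / "targets.tsv")
    write_symbol_map(bundle.symbol_map, outdir / "symbol_map.tsv")
    for gs in bundle.disease_sources:
        write_gene_list(gs, outdir / f"disease_{gs.name}.txt")
    write_weighted_edges(bundle.ppi_edges, outdir / "ppi_edges.tsv")
    write_gmt(bundle.annotations, outdir / "annotations.gmt")
    write_de_table(bundle.de_table, outdir / "de_table.tsv")
    bundle.ledger.to_json(outdir / "ledger.json")
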