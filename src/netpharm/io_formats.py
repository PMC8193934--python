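"""Readers and writers for every external format the pipeline touches.

All other modules operate on the in-memory domain types defined here (and in
:mod:`netpharm.geneset_ops`); nothing else parses files. TSV is the canonical
tabular dialect, with CSV accepted via ``dialect="csv"``. Gene symbols are
uppercased on ingestion everywhere.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import FormatError, ValidationError
from .geneset_ops import GeneSet

logger = logging.getLogger(__name__)

_DELIMS = {"tsv": "\t", "csv": ","}


def _sep(dialect: str) -> str:
    try:
        return _DELIMS[dialect]
    except KeyError:
        raise FormatError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")


# ---------------------------------------------------------------------------
# Ingredient tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IngredientRecord:
    """One molecule of one herb with its screening properties.

    ``ob`` is oral bioavailability as a percentage on the 0-100 scale; ``dl``
    is unitless drug-likeness on the 0-1 scale (TCMSP conventions).
    """

    herb_id: str
    molecule_id: str
    molecule_name: str
    ob: float
    dl: float


@dataclass(frozen=True)
class IngredientTable:
    rows: tuple[IngredientRecord, ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        bad: list[str] = []
        for rec in self.rows:
            key = (rec.herb_id, rec.molecule_id)
            if key in seen:
                raise ValidationError(f"duplicate (herb, molecule) pair {key}")
            seen.add(key)
            if not (math.isfinite(rec.ob) and 0.0 <= rec.ob <= 100.0):
                bad.append(f"{key}: OB={rec.ob}")
            if not (math.isfinite(rec.dl) and 0.0 <= rec.dl <= 1.0):
                bad.append(f"{key}: DL={rec.dl}")
        if bad:
            raise ValidationError("OB/DL out of range: " + "; ".join(bad))

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[IngredientRecord]:
        return iter(self.rows)

    @property
    def herbs(self) -> tuple[str, ...]:
        out: list[str] = []
        for rec in self.rows:
            if rec.herb_id not in out:
                out.append(rec.herb_id)
        return tuple(out)


DEFAULT_INGREDIENT_HEADER = {
    "herb_id": "herb",
    "molecule_id": "molecule_id",
    "molecule_name": "molecule_name",
    "ob": "ob",
    "dl": "dl",
}


def read_ingredient_table(
    path: str | Path,
    dialect: str = "tsv",
    header_map: Mapping[str, str] | None = None,
) -> IngredientTable:
    """Read a herb/molecule/OB/DL table.

    ``header_map`` maps the canonical field names (``herb_id``,
    ``molecule_id``, ``molecule_name``, ``ob``, ``dl``) to the column names
    actually present in the file. Rows with non-numeric OB or DL are rejected
    with a row-numbered error report (row numbers count data rows from 1).
    """
    hmap = dict(DEFAULT_INGREDIENT_HEADER)
    if header_map:
        hmap.update(header_map)
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str)
    missing = [col for col in hmap.values() if col not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    bad_rows: list[str] = []
    rows: list[IngredientRecord] = []
    for i, raw in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, raw))
        try:
            ob = float(row[hmap["ob"]])
            dl = float(row[hmap["dl"]])
            if not (math.isfinite(ob) and math.isfinite(dl)):
                raise ValueError
        except (TypeError, ValueError):
            bad_rows.append(
                f"row {i}: OB={row[hmap['ob']]!r} DL={row[hmap['dl']]!r}"
            )
            continue
        rows.append(
            IngredientRecord(
                herb_id=str(row[hmap["herb_id"]]).strip(),
                molecule_id=str(row[hmap["molecule_id"]]).strip(),
                molecule_name=str(row[hmap["molecule_name"]]).strip(),
                ob=ob,
                dl=dl,
            )
        )
    if bad_rows:
        raise FormatError(
            f"{path}: non-numeric OB/DL values: " + "; ".join(bad_rows)
        )
    return IngredientTable(rows=tuple(rows))


def write_ingredient_table(
    table: IngredientTable, path: str | Path, dialect: str = "tsv"
) -> None:
    df = pd.DataFrame(
        [
            (r.herb_id, r.molecule_id, r.molecule_name, r.ob, r.dl)
            for r in table.rows
        ],
        columns=["herb", "molecule_id", "molecule_name", "ob", "dl"],
    )
    df.to_csv(path, sep=_sep(dialect), index=False)


# ---------------------------------------------------------------------------
# Ingredient -> target maps and symbol maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetRecord:
    molecule_id: str
    target_name: str
    gene_symbol: str  # empty string when unmapped


@dataclass(frozen=True)
class TargetMapTable:
    rows: tuple[TargetRecord, ...]

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[TargetRecord]:
        return iter(self.rows)

    def by_molecule(self) -> dict[str, tuple[TargetRecord, ...]]:
        out: dict[str, list[TargetRecord]] = {}
        for rec in self.rows:
            out.setdefault(rec.molecule_id, []).append(rec)
        return {k: tuple(v) for k, v in out.items()}


def read_target_map(path: str | Path, dialect: str = "tsv") -> TargetMapTable:
    """Read a molecule -> protein-target table (2 or 3 columns).

    Columns: molecule_id, target_name, and optionally gene_symbol. Duplicate
    (molecule_id, gene_symbol) pairs are collapsed on load; rows without a
    symbol are kept once per (molecule, target name).
    """
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str).fillna("")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected at least 2 columns")
    cols = list(df.columns)
    rows: list[TargetRecord] = []
    seen_mapped: set[tuple[str, str]] = set()
    seen_unmapped: set[tuple[str, str]] = set()
    for raw in df.itertuples(index=False):
        mol = str(raw[0]).strip()
        name = str(raw[1]).strip()
        sym = str(raw[2]).strip().upper() if len(cols) >= 3 else ""
        if sym:
            if (mol, sym) in seen_mapped:
                continue
            seen_mapped.add((mol, sym))
        else:
            if (mol, name) in seen_unmapped:
                continue
            seen_unmapped.add((mol, name))
        rows.append(TargetRecord(mol, name, sym))
    return TargetMapTable(rows=tuple(rows))


def write_target_map(
    table: TargetMapTable, path: str | Path, dialect: str = "tsv"
) -> None:
    df = pd.DataFrame(
        [(r.molecule_id, r.target_name, r.gene_symbol) for r in table.rows],
        columns=["molecule_id", "target_name", "gene_symbol"],
    )
    df.to_csv(path, sep=_sep(dialect), index=False)


def read_symbol_map(path: str | Path, dialect: str = "tsv") -> dict[str, str]:
    """Two-column target-name -> gene-symbol mapping (UniProt stand-in)."""
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=_sep(dialect))
        for i, parts in enumerate(reader, start=1):
            if not parts or (parts[0].startswith("#")):
                continue
            if len(parts) < 2:
                raise FormatError(f"{path}:{i}: expected 2 columns")
            mapping[parts[0].strip()] = parts[1].strip().upper()
    return mapping


def write_symbol_map(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(mapping):
            fh.write(f"{name}\t{mapping[name]}\n")


# ---------------------------------------------------------------------------
# Gene lists
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path, source_label: str) -> GeneSet:
    """Read a one-symbol-per-line gene list.

    Blank lines and ``#`` comments are skipped; symbols are uppercased,
    whitespace-stripped, and deduplicated.
    """
    symbols: set[str] = set()
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            symbols.add(token.upper())
    if not symbols:
        raise FormatError(f"{path}: no gene symbols after filtering")
    return GeneSet(name=source_label, symbols=frozenset(symbols),
                   sources=(source_label,))


def write_gene_list(genes: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for symbol in sorted(genes.symbols):
            fh.write(symbol + "\n")


# ---------------------------------------------------------------------------
# Weighted edge lists (STRING-style)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightedEdgeList:
    """Undirected, deduplicated, thresholded protein association edges.

    ``score_scale`` records the scale the file used: ``"unit"`` for
    confidences in [0, 1] or ``"raw1000"`` for STRING's 0-999 integers.
    Scores are stored as read (original scale).
    """

    edges: tuple[tuple[str, str, float], ...]
    score_scale: str = "unit"

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self) -> Iterator[tuple[str, str, float]]:
        return iter(self.edges)

    @property
    def nodes(self) -> frozenset[str]:
        out: set[str] = set()
        for a, b, _ in self.edges:
            out.add(a)
            out.add(b)
        return frozenset(out)

    def unit_scores(self) -> tuple[tuple[str, str, float], ...]:
        if self.score_scale == "unit":
            return self.edges
        return tuple((a, b, s / 1000.0) for a, b, s in self.edges)


def read_weighted_edges(
    path: str | Path,
    threshold_unit_interval: float = 0.7,
    dialect: str = "tsv",
) -> WeightedEdgeList:
    """Read a (node_a, node_b, combined_score) edge list and threshold it.

    The score scale is auto-detected: any score above 1 marks the file as
    0-999-style, in which case the unit-interval threshold is multiplied by
    1000. Edges at the threshold are kept (>= comparison). Self-loops are
    dropped, and duplicate unordered pairs are collapsed keeping the maximum
    score.
    """
    raw: list[tuple[str, str, float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=_sep(dialect))
        for i, parts in enumerate(reader, start=1):
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 3:
                raise FormatError(f"{path}:{i}: expected at least 3 columns")
            try:
                score = float(parts[2])
            except ValueError:
                if i == 1:  # header row
                    continue
                raise FormatError(f"{path}:{i}: non-numeric score {parts[2]!r}")
            if score < 0:
                raise FormatError(f"{path}:{i}: negative score {score}")
            raw.append((parts[0].strip().upper(), parts[1].strip().upper(), score))

    scale = "raw1000" if any(s > 1.0 for _, _, s in raw) else "unit"
    cutoff = (
        threshold_unit_interval * 1000.0
        if scale == "raw1000"
        else threshold_unit_interval
    )

    best: dict[tuple[str, str], float] = {}
    n_self = 0
    for a, b, s in raw:
        if a == b:
            n_self += 1
            continue
        key = (a, b) if a <= b else (b, a)
        if s > best.get(key, -1.0):
            best[key] = s
    kept = sorted(
        (a, b, s) for (a, b), s in best.items() if s >= cutoff
    )
    logger.info(
        "%s: %d rows -> %d unique pairs, %d self-loops dropped, "
        "%d edges >= %.3g (%s scale)",
        path, len(raw), len(best), n_self, len(kept), cutoff, scale,
    )
    return WeightedEdgeList(edges=tuple(kept), score_scale=scale)


def threshold_edges(
    edges: WeightedEdgeList, threshold_unit_interval: float = 0.7
) -> WeightedEdgeList:
    """Apply the confidence threshold (>=, unit scale) to an in-memory edge
    list; the file reader applies the same rule."""
    kept = tuple(
        edge
        for edge, (_, _, unit_score) in zip(edges.edges, edges.unit_scores())
        if unit_score >= threshold_unit_interval
    )
    return WeightedEdgeList(edges=kept, score_scale=edges.score_scale)


def write_weighted_edges(
    edges: WeightedEdgeList, path: str | Path, dialect: str = "tsv"
) -> None:
    sep = _sep(dialect)
    with open(path, "w") as fh:
        fh.write(sep.join(["protein1", "protein2", "combined_score"]) + "\n")
        for a, b, s in edges.edges:
            fh.write(sep.join([a, b, repr(s)]) + "\n")


# ---------------------------------------------------------------------------
# GMT annotation sets
# ---------------------------------------------------------------------------

NAMESPACES = ("BP", "CC", "MF", "KEGG")


@dataclass(frozen=True)
class AnnotationTerm:
    term_id: str
    term_name: str
    namespace: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ValidationError(
                f"term {self.term_id}: namespace {self.namespace!r} "
                f"not in {NAMESPACES}"
            )
        if not self.members:
            raise ValidationError(f"term {self.term_id}: no member genes")
        object.__setattr__(
            self, "members", frozenset(m.upper() for m in self.members)
        )


@dataclass(frozen=True)
class AnnotationSet:
    terms: Mapping[str, AnnotationTerm]

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[AnnotationTerm]:
        return iter(self.terms.values())

    @property
    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for term in self.terms.values():
            out |= term.members
        return frozenset(out)


def read_gmt(path: str | Path, default_namespace: str = "BP") -> AnnotationSet:
    """Read a Broad-dialect GMT file.

    Line format: ``term_id<TAB>description<TAB>gene1<TAB>gene2...``. The
    namespace tag (BP/CC/MF/KEGG) may be encoded as a ``TAG|description``
    prefix in the description field; otherwise ``default_namespace`` applies.
    """
    terms: dict[str, AnnotationTerm] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{i}: GMT line needs >= 3 fields, got {len(parts)}"
                )
            term_id, desc = parts[0], parts[1]
            namespace = default_namespace
            if "|" in desc:
                tag, rest = desc.split("|", 1)
                if tag in NAMESPACES:
                    namespace, desc = tag, rest
            members = frozenset(p.strip().upper() for p in parts[2:] if p.strip())
            if not members:
                raise FormatError(f"{path}:{i}: term {term_id} has no members")
            if term_id in terms:
                raise FormatError(f"{path}:{i}: duplicate term id {term_id}")
            terms[term_id] = AnnotationTerm(term_id, desc, namespace, members)
    return AnnotationSet(terms=terms)


def write_gmt(annotations: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term_id in sorted(annotations.terms):
            term = annotations.terms[term_id]
            fields = [term.term_id, f"{term.namespace}|{term.term_name}"]
            fields.extend(sorted(term.members))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Differential-expression tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DETable:
    """Differential-expression results: gene, log2fc, pvalue, padj.

    ``padj >= pvalue`` is *not* enforced: some DE tools emit adjusted values
    capped or reordered in ways that break the inequality row-wise; both are
    only required to lie in [0, 1].
    """

    frame: pd.DataFrame = field(compare=False)

    REQUIRED = ("gene", "log2fc", "pvalue", "padj")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"DE table missing column(s) {missing}")
        if df["gene"].duplicated().any():
            dups = df.loc[df["gene"].duplicated(), "gene"].tolist()[:5]
            raise ValidationError(f"duplicate gene symbols in DE table: {dups}")
        for col in ("pvalue", "padj"):
            vals = df[col].to_numpy(dtype=float)
            if ((vals < 0) | (vals > 1)).any() or not pd.notna(vals).all():
                raise ValidationError(f"DE table column {col} outside [0, 1]")
        if not pd.notna(df["log2fc"].to_numpy(dtype=float)).all():
            raise ValidationError("DE table log2fc contains non-finite values")
        df = df.copy()
        df["gene"] = df["gene"].str.upper()
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.frame)


def read_de_table(path: str | Path, dialect: str = "tsv") -> DETable:
    df = pd.read_csv(path, sep=_sep(dialect))
    df.columns = [str(c).lower() for c in df.columns]
    return DETable(frame=df)


def write_de_table(table: DETable, path: str | Path, dialect: str = "tsv") -> None:
    table.frame.to_csv(path, sep=_sep(dialect), index=False)


# ---------------------------------------------------------------------------
# Graph and generic table export
# ---------------------------------------------------------------------------

GRAPH_FORMATS = ("graphml", "sif", "tsv")


def write_graph(graph: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Export a graph as GraphML (lossless for declared attributes), SIF, or
    a plain edge TSV."""
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for a, b, data in sorted(graph.edges(data=True)):
                rel = data.get("interaction", "pp")
                fh.write(f"{a}\t{rel}\t{b}\n")
            for node in sorted(graph.nodes):
                if graph.degree(node) == 0:
                    fh.write(f"{node}\n")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tattributes\n")
            for a, b, data in sorted(graph.edges(data=True)):
                attrs = ";".join(f"{k}={v}" for k, v in sorted(data.items()))
                fh.write(f"{a}\t{b}\t{attrs}\n")
    else:
        raise FormatError(f"unknown graph format {fmt!r}; expected {GRAPH_FORMATS}")


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


def write_table(
    rows: Sequence[Mapping[str, object]] | pd.DataFrame,
    path: str | Path,
    dialect: str = "tsv",
) -> None:
    """Write a list of dict rows (or a DataFrame) as a delimited table."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep=_sep(dialect), index=False)
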