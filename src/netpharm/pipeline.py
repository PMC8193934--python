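"""End-to-end orchestration of the inference chain.

The stages run in a fixed order — screen, map targets, merge disease
sources, intersect, HIT network, PPI construction, centrality, hub
extraction, enrichment, and (when a DE table is supplied) DEG calling —
driven by a single :class:`RunConfig`. Every stage writes its intermediate
artifact to the output directory, and the machine-readable
:class:`RunReport` echoes the configuration plus all stage counts so each
number can be recomputed from the files on disk. A failing stage aborts the
run, names itself in the error, and leaves a ``FAILED`` marker next to the
partial outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .centrality import FEATURES, centrality_table
from .deg_filter import call_degs, deg_geneset
from .enrichment import enrich
from .errors import StageError
from .geneset_ops import GeneSet, intersect_drug_disease, merge_sources, venn_partition
from .hit_network import build_hit, per_herb_target_partition, representative_components
from .hub_extraction import extract_hubs
from .io_formats import (
    read_de_table,
    read_gene_list,
    read_gmt,
    read_ingredient_table,
    read_symbol_map,
    read_target_map,
    read_weighted_edges,
    write_gene_list,
    write_graph,
    write_ingredient_table,
    write_table,
)
from .ppi_graph import build_ppi
from .screening import map_targets, screen_ingredients

logger = logging.getLogger(__name__)

PAPER_DEFAULTS = {
    "ob_min": 20.0,
    "dl_min": 0.1,
    "ppi_confidence": 0.7,
    "filter_rounds": 2,
    "alpha": 0.05,
    "padj_max": 0.05,
    "lfc_min": 1.0,
}


@dataclass
class RunConfig:
    """Input paths, thresholds, and output location for one pipeline run."""

    ingredients: str
    targets: str
    symbol_map: str
    disease_lists: list[str]
    ppi_edges: str
    gmt: str
    outdir: str
    de_table: str | None = None
    ob_min: float = PAPER_DEFAULTS["ob_min"]
    dl_min: float = PAPER_DEFAULTS["dl_min"]
    ppi_confidence: float = PAPER_DEFAULTS["ppi_confidence"]
    filter_rounds: int = PAPER_DEFAULTS["filter_rounds"]
    alpha: float = PAPER_DEFAULTS["alpha"]
    padj_max: float = PAPER_DEFAULTS["padj_max"]
    lfc_min: float = PAPER_DEFAULTS["lfc_min"]
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (0 <= self.ob_min <= 100, "ob_min must be in [0, 100]"),
            (0 <= self.dl_min <= 1, "dl_min must be in [0, 1]"),
            (0 <= self.ppi_confidence <= 1, "ppi_confidence must be in [0, 1]"),
            (self.filter_rounds >= 0, "filter_rounds must be >= 0"),
            (0 < self.alpha < 1, "alpha must be in (0, 1)"),
            (0 < self.padj_max < 1, "padj_max must be in (0, 1)"),
            (self.lfc_min >= 0, "lfc_min must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    """Per-stage counts of a completed run plus the configuration echo."""

    version: str
    config: dict[str, Any]
    counts: dict[str, Any] = field(default_factory=dict)
    round_medians: list[dict[str, float]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True, default=list)


def config_for_directory(
    sim_dir: str | Path, outdir: str | Path, **overrides: Any
) -> RunConfig:
    """Build a RunConfig pointing at a directory of simulated inputs."""
    sim_dir = Path(sim_dir)
    kwargs: dict[str, Any] = dict(
        ingredients=str(sim_dir / "ingredients.tsv"),
        targets=str(sim_dir / "targets.tsv"),
        symbol_map=str(sim_dir / "symbol_map.tsv"),
        disease_lists=sorted(
            str(p) for p in sim_dir.glob("disease_*.txt")
        ),
        ppi_edges=str(sim_dir / "ppi_edges.tsv"),
        gmt=str(sim_dir / "annotations.gmt"),
        de_table=str(sim_dir / "de_table.tsv"),
        outdir=str(outdir),
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


def run_all(config: RunConfig) -> RunReport:
    """Execute the full inference chain; see the module docstring."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    report = RunReport(version=__version__, config=config.to_dict())
    counts = report.counts
    stage = "init"
    try:
        stage = "screen"
        table = read_ingredient_table(config.ingredients)
        active = screen_ingredients(table, ob_min=config.ob_min,
                                    dl_min=config.dl_min)
        write_ingredient_table(active, outdir / "active_ingredients.tsv")
        counts["ingredients_in"] = len(table)
        counts["ingredients_active"] = len(active)

        stage = "map_targets"
        target_map = read_target_map(config.targets)
        symbol_map = read_symbol_map(config.symbol_map)
        components = map_targets(active, target_map, symbol_map)
        drug_targets = components.union_geneset()
        write_gene_list(drug_targets, outdir / "drug_targets.txt")
        counts["drug_target_union"] = len(drug_targets)
        counts["unmapped_target_rows"] = components.n_unmapped_names

        stage = "disease_merge"
        sources = [
            read_gene_list(path, source_label=Path(path).stem)
            for path in config.disease_lists
        ]
        disease = merge_sources(sources, name="disease")
        write_gene_list(disease, outdir / "disease_genes.txt")
        counts["disease_sources"] = len(sources)
        counts["disease_union"] = len(disease)
        if 2 <= len(sources) <= 6:
            venn = venn_partition(sources)
            write_table(
                [
                    {"region": "&".join(sorted(region)), "count": n}
                    for region, n in sorted(
                        venn.counts.items(), key=lambda kv: sorted(kv[0])
                    )
                ],
                outdir / "venn_regions.tsv",
            )

        stage = "intersect"
        putative = intersect_drug_disease(drug_targets, disease)
        write_gene_list(putative, outdir / "putative_targets.txt")
        counts["putative_targets"] = len(putative)

        stage = "hit_network"
        hit = build_hit(components, putative)
        write_graph(hit.graph, outdir / "hit_network.graphml")
        per_herb = per_herb_target_partition(hit)
        write_table(
            [
                {"herb": herb, "n_targets": len(genes),
                 "targets": ";".join(sorted(genes))}
                for herb, genes in sorted(per_herb.items())
            ],
            outdir / "per_herb_targets.tsv",
        )
        counts["hit_herbs"] = len(hit.herbs)
        counts["hit_ingredients"] = len(hit.ingredients)
        counts["hit_genes"] = len(hit.genes)

        stage = "ppi"
        edges = read_weighted_edges(
            config.ppi_edges, threshold_unit_interval=config.ppi_confidence
        )
        ppi = build_ppi(edges, restrict_to=putative)
        write_graph(ppi, outdir / "ppi_network.graphml")
        counts["ppi_nodes"] = ppi.number_of_nodes()
        counts["ppi_edges"] = ppi.number_of_edges()

        stage = "centrality"
        ctable = centrality_table(ppi, snapshot_id="full_ppi")
        ctable.frame.to_csv(outdir / "centrality.tsv", sep="\t")

        stage = "hubs"
        hubs, rounds = extract_hubs(ppi, rounds=config.filter_rounds)
        write_gene_list(hubs, outdir / "hub_genes.txt")
        write_table(
            [
                {
                    "round": r.round_index,
                    "n_in": r.n_in,
                    **{f"median_{f}": r.medians[f] for f in FEATURES},
                    "n_out": r.n_out,
                    "stop_reason": r.stop_reason,
                }
                for r in rounds
            ],
            outdir / "hub_rounds.tsv",
        )
        counts["hub_genes"] = len(hubs)
        counts["hub_rounds_run"] = len(rounds)
        report.round_medians = [dict(r.medians) for r in rounds]

        stage = "representatives"
        representatives = representative_components(hit, hubs)
        write_table(
            [{"herb": h, "molecule_id": m}
             for h, m in sorted(representatives.items())],
            outdir / "representative_components.tsv",
        )
        counts["herbs_with_representative"] = len(representatives)

        stage = "enrich"
        annotations = read_gmt(config.gmt)
        rows = enrich(hubs, annotations, alpha=config.alpha)
        write_table(
            [dataclasses.asdict(r) for r in rows], outdir / "enrichment.tsv"
        )
        counts["terms_tested"] = len(rows)
        counts["terms_significant"] = sum(r.significant for r in rows)

        if config.de_table:
            stage = "deg_filter"
            de = read_de_table(config.de_table)
            calls, summary = call_degs(
                de, padj_max=config.padj_max, lfc_min=config.lfc_min
            )
            write_table(
                [dataclasses.asdict(c) for c in calls], outdir / "deg_calls.tsv"
            )
            for direction in ("up", "down"):
                write_gene_list(
                    deg_geneset(calls, direction),
                    outdir / f"deg_{direction}.txt",
                )
            counts["deg_up"] = summary.n_up
            counts["deg_down"] = summary.n_down
            counts["deg_total"] = summary.n_de
    except Exception as exc:
        failed_marker.write_text(f"stage: {stage}\nerror: {exc}\n")
        raise StageError(stage, exc) from exc

    report.to_json(outdir / "run_report.json")
    logger.info("pipeline complete; report written to %s", outdir)
    return report
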