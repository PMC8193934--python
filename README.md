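# netpharm

Network-pharmacology inference for multi-herb formulas. Given TCMSP-style
ingredient tables, ingredient–target maps, multi-database disease gene
lists, STRING-style interaction scores, GMT annotations and a
differential-expression table, the package runs the standard inference
chain used to explain how a herbal formula might act on a disease:

1. **Ingredient screening** — keep compounds with oral bioavailability
   OB ≥ 20 % and drug-likeness DL ≥ 0.1 (both inclusive).
2. **Target mapping** — translate protein targets of the surviving
   compounds into human gene symbols via a table-driven symbol map.
3. **Disease-gene merging** — union the per-database disease lists, with
   full Venn region counts and per-symbol provenance.
4. **Putative targets** — intersect drug targets with disease genes.
5. **Herb–ingredient–target (HIT) network** — the tripartite graph linking
   herbs, compounds and putative targets; per-herb target partitions and
   one representative compound per herb chosen by hub-gene degree.
6. **PPI graph** — the induced interaction network on the putative targets
   at combined-score confidence ≥ 0.7, without disconnected nodes.
7. **Hub extraction** — six centrality features per node — betweenness
   (BC), closeness (CC), degree (DC), eigenvector (EC), local average
   connectivity (LAC) and network centrality (NC, summed edge clustering
   coefficients) — computed twice in an iterative filter that keeps only
   nodes **strictly above the median** of *all six* features each round.
8. **Enrichment** — hypergeometric over-representation of the hub set
   against GO/KEGG-style terms, Benjamini–Hochberg adjusted (significant at
   padj < 0.05).
9. **DEG calling** — up/down classification of a DE table at padj < 0.05
   and |log2FC| > 1 (both strict).

For node `v` with neighborhood `N(v)`, the two less common features are

```
LAC(v) = (1/|N(v)|) * Σ_{w ∈ N(v)} deg_{G[N(v)]}(w)
NC(v)  = Σ_{u ∈ N(v)} z_vu / min(deg v − 1, deg u − 1)   (0 when the denominator is 0)
```

where `G[N(v)]` is the subgraph induced by `v`'s neighbors and `z_vu`
counts common neighbors of `v` and `u`.

Because the real inputs are snapshots of external databases, the package
ships a first-class synthetic-data module: every input can be generated
with a **ledger** of planted ground truth (exact screen pass-set, disease
union, drug–disease intersection, dense PPI module, enriched term, DEG
split), so every stage is testable offline.

## Worked example

Recover a planted dense module from a 200-node interaction network:

```python
from netpharm.synthetic_data import gen_ppi
from netpharm.ppi_graph import build_ppi
from netpharm.hub_extraction import extract_hubs

edges, ledger = gen_ppi(n_background=170, module_size=30, seed=1)
graph = build_ppi(edges)
hubs, rounds = extract_hubs(graph, rounds=2)
for r in rounds:
    meds = ", ".join(f"{k}={v:.3f}" for k, v in r.medians.items())
    print(f"round {r.round_index}: {r.n_in} -> {r.n_out} nodes  ({meds})")
module = set(ledger.module_nodes)
print(f"hubs: {len(hubs)}  precision vs planted module: "
      f"{len(hubs.symbols & module) / len(hubs):.2f}")
```

prints

```
round 1: 200 -> 43 nodes  (bc=125.787, cc=0.395, dc=9.000, ec=0.009, lac=0.400, nc=0.509)
round 2: 43 -> 12 nodes  (bc=6.052, cc=0.575, dc=16.000, ec=0.186, lac=10.316, nc=11.067)
hubs: 12  precision vs planted module: 1.00
```

Each line reports one filter round: the node count before and after, and
the six per-round feature medians that every survivor strictly exceeds.
All 12 extracted hub genes belong to the 30-node planted module.

The same chain runs end-to-end from the command line:

```sh
netpharm simulate --seed 7 --outdir sim/     # inputs + ledger.json
netpharm run --config run.yaml               # screen ... enrich ... deg-filter
```

with subcommands (`screen`, `map-targets`, `disease-merge`, `intersect`,
`hit-net`, `ppi-filter`, `centrality`, `hubs`, `enrich`, `deg-filter`) for
individual stages. `run` writes every intermediate artifact (gene lists,
GraphML networks, centrality and enrichment tables) plus a JSON run report
whose counts are all recomputable from the files on disk.

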