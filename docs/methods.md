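# Methods

## The inference chain

The package models a common design in herbal network pharmacology: a
formula's candidate compounds are reduced to a pharmacokinetically
plausible "active" subset, linked to human gene targets, intersected with
disease-associated genes, and the resulting protein-interaction subnetwork
is mined for hub genes whose annotations explain the formula's putative
mechanism. Every stage consumes and produces explicit domain objects
(ingredient tables, named gene sets, tripartite networks, weighted PPI
graphs, centrality tables), so each step can be validated in isolation.

### Screening

Compounds pass when OB ≥ `ob_min` (percent, default 20) **and**
DL ≥ `dl_min` (unitless, default 0.1). Both thresholds are inclusive: the
screening criterion is stated as "greater or equal", and the boundary row
(OB = 20, DL = 0.1) is retained. Screening preserves row order, which
makes it idempotent, and raising either threshold can only shrink the
result (a property the suite checks).

### Target mapping and gene-set algebra

Protein target names are translated to uppercase human gene symbols by a
two-column mapping table (a local stand-in for a live protein-knowledge
lookup; remote queries are deliberately out of scope). Names without a
mapping are dropped with a logged count rather than guessed — target
vocabularies routinely include non-human or ambiguous entries and silent
guessing would contaminate the downstream intersection. Symbols are
compared as exact uppercase strings; alias resolution belongs in the
mapping table, not the set algebra. Merges keep per-symbol provenance so
the Venn partition (all `2^k − 1` disjoint regions, 2–6 sets) can be
recomputed from the merged object alone.

### PPI construction

Edge lists are STRING-shaped: `node_a`, `node_b`, `combined_score`. The
score scale is auto-detected (any score above 1 implies the 0–999 integer
convention, in which case the unit-interval threshold is multiplied by
1000); the confidence filter keeps ties at the threshold (≥ 0.7 by
default). Duplicate unordered pairs collapse to their maximum score and
self-loops are removed. The analysis graph is the induced subgraph on the
putative targets with isolated nodes removed — downstream centralities are
meaningless for degree-zero nodes, and the source convention is a network
"without disconnected nodes".

## Centrality features

Six per-node features drive hub extraction (definitions in the README).
Scale conventions matter because the hub filter compares nodes to medians:

- **BC** is unnormalized (path-pair units) and **DC** is a raw neighbor
  count. Hub-filter medians on interactome subnetworks are conventionally
  reported on these raw scales, and normalization would not change the
  filter's decisions (it is a per-round monotone rescaling); a
  `normalized=True` flag exposes the `(n−1)(n−2)/2` and `(n−1)` rescalings
  for interoperability.
- **CC** is component-restricted: `(|C_v| − 1) / Σ d(v,u)` over `v`'s
  component, 0 for singletons, always in [0, 1].
- **EC** is the non-negative principal eigenvector of the adjacency
  matrix with unit Euclidean norm. Power iteration runs on `A + I` — the
  unit shift leaves eigenvectors unchanged but makes the Perron root
  strictly dominant, so bipartite graphs (whose adjacency spectrum is
  symmetric about zero and makes plain power iteration oscillate) converge
  as well. Iteration starts from the uniform positive vector and stops
  when successive normalized iterates differ by < 1e-10 in max-norm
  (at most 10,000 iterations; exceeding that raises an error rather than
  returning an unconverged vector).
- **LAC/NC** follow the induced-subgraph and edge-clustering-coefficient
  definitions. The ECC denominator can vanish on pendant edges
  (`min(deg−1) = 0`); the convention here is ECC = 0 for such edges.
  Alternative conventions (skip the edge, use 1) exist but change nothing
  for the filter's intended behavior of down-weighting pendant structure.

Betweenness uses Brandes' dependency accumulation (exact, O(nm) for
unweighted graphs); the literal all-shortest-paths enumeration survives
only as a test oracle. The suite checks all six features against
independent brute-force implementations on **every** connected graph with
up to 7 nodes (995 non-isomorphic graphs) to 1e-8, plus closed-form cases
(complete graphs, stars, cycles, trees) and a hand-derived 10-node
worked fixture (5-clique with pendant leaves).

## Hub extraction

Each round computes the six features on the current graph, takes
per-feature medians over the current nodes (even counts use the midpoint
of the two central order statistics — the natural reading when reported
medians of integer-valued features are fractional), and retains nodes
strictly exceeding **all six** medians. Strictness plus the conjunction
give a hard guarantee: at most `⌈(n−1)/2⌉` nodes can strictly exceed any
single median, so each round at least halves the graph. Nodes isolated by
a round's deletions are dropped before the next round, and centralities
are **recomputed** on the shrunken graph each round (the alternative —
reusing round-1 values — would make the second median vector identical to
a quantile of the first, which is not how two-stage topological filters
are reported). The default is two rounds.

A round that would empty the graph stops iteration and returns the
previous round's node set (`stop_reason = would_empty`): fully symmetric
graphs have constant feature vectors, no node strictly exceeds a constant's
median, and a pipeline must end with a usable hub set. A
`min_features = k` relaxation of the six-way conjunction is available but
defaults to 6.

## Enrichment

Over-representation uses the hypergeometric upper tail
`P(X ≥ k)` for `X ~ Hypergeometric(N, K, n)` (equivalently one-tailed
Fisher), evaluated through the scipy survival function (log-space
internally, stable for large universes) and verified against exhaustive
draw-counting on the full `N ≤ 20` grid. The universe defaults to all
genes in the annotation file (overridable), query and terms are
intersected with it first, and BH adjustment runs per namespace
(BP/CC/MF/KEGG) to match how GO panels are reported; a pooled mode exists.
Significance is `padj < 0.05`, strict. Under null annotations the
discrete hypergeometric p-values are conservative, so the family-wise
false-positive rate sits at or below the nominal level — the calibration
test bounds it by nominal + 3σ binomial error over 100 replicates.

## DEG calling

Strict thresholds on both axes (`padj < 0.05`, `|log2FC| > 1`), reading
the fold-change criterion as absolute-valued — both up- and down-regulated
sets are defined, which requires the two-sided reading. Boundary rows are
"unchanged". The differential test itself is upstream; any table with
gene/log2fc/pvalue/padj columns is accepted, and `padj ≥ pvalue` is not
enforced row-wise because adjusted values from some tools violate it after
capping.

## Synthetic data and what it does (not) show

Generators are pure functions of parameters and seed, and each returns a
ledger that pins the expected output of every deterministic stage:

- **Ingredients**: passers draw OB ~ U(20, 60), DL ~ U(0.1, 0.6); one
  passer is pinned at the exact boundary; failers violate ≥ 1 bound. The
  pass fraction defaults to 0.4.
- **Disease sources**: five lists whose union is exact by construction;
  a redundancy parameter (mean source memberships per gene, default 1.6)
  controls overlap.
- **PPI**: planted-partition graph — 30 module nodes wired at p = 0.8,
  170 background nodes at p = 0.05, cross edges at p = 0.02, confidences
  U(0.7, 0.999), plus optional sub-threshold decoy rows that the reader
  must drop. At these defaults the module dominates every centrality
  feature and two-round extraction recovers it with precision ≈ 1 and
  recall ≈ 0.3–0.5 (the filter keeps the module's densest core).
- **Annotations**: null terms drawn uniformly from the universe; one
  planted term overlaps the designated query at 80 % of its size.
- **DE table**: exactly `n_up = 141` and `n_down = 643` planted calls
  among 15,000 genes (defaults chosen at a realistic transcriptome-wide
  DEG split), every other row violating a threshold.

The composite `paperlike` preset scales like a single-formula study — 200
candidate compounds, a 300-gene target union, a 500-gene disease union
sharing exactly 200 genes with it, and a 200-node PPI graph — so a full
end-to-end run takes seconds on one core. These sizes are the package's
test conditions, chosen once; all downstream checks run against them
unchanged.

What passing tests show: the logic of every stage — thresholds, set
algebra, graph construction, centrality mathematics, the filter's order
statistics, the enrichment combinatorics — is correct, deterministic and
ledger-consistent. What they do not show: behavior on real TCMSP/STRING
marginals (degree heavy tails, score mixtures, symbol aliasing noise), or
recovery guarantees when the "module" is not assortatively dense. Hub
counts on uniform random graphs also say nothing about biological hubs.

## Numerical and degenerate-input conventions

- Even-length medians: midpoint convention (`numpy` default).
- EC on edgeless graphs is 0 in the aggregate table (no eigenvector mass
  without edges); calling the EC routine directly on such graphs is an
  error.
- EC on disconnected graphs concentrates on the component with the
  largest Perron root; other components get values near 0. This only
  sharpens the hub filter's preference for the dominant component.
- Representative-compound ties break to the lexicographically smallest
  molecule id (logged); no principled ordering exists without potency
  data, so the rule is chosen for determinism.
- Empty intersections, empty unions, empty graphs and empty queries are
  pipeline-stopping errors, not silent empties; the orchestrator names the
  failing stage and leaves a `FAILED` marker.

## Known limitations

- Weighted/directed centralities are out of scope; confidences are kept
  as attributes but do not enter the features.
- No GO graph topology (parent propagation) and no ranked-list (GSEA)
  enrichment; ORA only.
- The screening stage consumes OB/DL values; it does not predict them
  from structure.
- Venn output is counts/members only; no proportional-area rendering.
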