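# netpharm

A network-pharmacology analysis pipeline for multi-compound (herbal) drugs.
Given a compound table with pharmacokinetic attributes, a compound→target
association table, multi-source disease gene lists, a PPI edge table and a
term annotation map, it identifies candidate therapeutic targets and the
topological hub genes through which a formula is likely to act — the
computational half of a target-identification study, reimplemented as a
tested, reusable library with a CLI.

Intended users: systems-biology and TCM (traditional Chinese medicine)
researchers who have exported their database tables (ingredient catalogues,
disease-gene lists, a STRING-style PPI subnetwork, GO/KEGG annotations) and
want the downstream analysis to be deterministic, scriptable and unit-tested
rather than a chain of point-and-click tools.

## Method

1. **Compound screen.** Keep ingredient *i* when
   `OB_i ≥ 30` **and** (`DL_i ≥ 0.18` **or** `score_i ≥ 20`), where OB is
   oral bioavailability (%), DL drug-likeness and score a source-database
   relevance score (all thresholds inclusive, configurable; a record without
   a score is judged on DL alone).
2. **Target/disease intersection.** Drug targets T = union of the screened
   compounds' catalogued targets; disease genes D = union of the per-source
   lists; candidate targets = T ∩ D. Screened compounds hitting ≥ 1
   intersection gene are the *effective* compounds, assembled into a
   herb–compound–target tripartite network and ranked by target degree.
3. **Hub (core) extraction.** On the primary PPI graph compute six node
   metrics — degree DC, betweenness BC (unnormalized,
   BC(v) = Σ_{s<t} σ_st(v)/σ_st), closeness CC(v) = |R(v)| / Σ_{u∈R(v)} d(v,u),
   eigenvector EC (leading adjacency eigenvector per component, unit 2-norm),
   local average connectivity LAC(v) = 2·e(N(v))/|N(v)|, and network
   centrality NC(v) = Σ_{u∈N(v)} z_uv / min(deg u − 1, deg v − 1) — keep the
   nodes **strictly above the median in all six**, and repeat on the induced
   subgraph (two steps by default). The surviving subgraph is the core PPI
   network.
4. **Enrichment.** For each annotation term, P(X ≥ k) with
   X ~ Hypergeometric(N, K, n) (universe N, term size K, query n, hits k),
   Benjamini–Hochberg FDR within each category (BP/CC/MF/KEGG), significance
   at q ≤ 0.05, reported top-10 per GO category and top-30 KEGG.

A synthetic-data module generates every input with the structure the
analysis assumes — threshold-straddling compound tables, overlapping disease
sources, a PPI graph with a planted dense core, an annotation map with one
planted enriched term — so the whole pipeline is testable offline. A
body-surface-area dose converter (`DB(rat) = DA(human) × 7/388`) is included
for translating a human daily dose to the rat scale.

## Worked example

```python
from netpharm import (gen_bundle, screen_compounds, collect_targets, merge_sources,
                      intersect_targets, effective_compounds, extract_core, enrich)
from netpharm.records import GeneSet

bundle = gen_bundle(seed=7)   # 140 compounds, 7 disease sources, 150-node PPI

screened = screen_compounds(list(bundle.compound_table))
targets = collect_targets(screened, bundle.associations)
disease = merge_sources(bundle.disease_sources)
candidates = intersect_targets(targets, disease)
effective = effective_compounds(candidates, bundle.associations, screened)
print(f"{len(screened)}/{len(bundle.compound_table)} compounds pass the screen")
print(f"{len(targets)} targets, {len(disease)} disease genes, "
      f"{len(candidates)} intersection genes, {len(effective)} effective compounds")

result = extract_core(bundle.ppi, steps=2)
core = set(result.core.nodes)
jaccard = len(core & bundle.planted_core) / len(core | bundle.planted_core)
print(f"core: {len(core)} nodes (planted 23); Jaccard with planted core = {jaccard:.2f}")

rows = enrich(GeneSet.from_symbols("core", core), bundle.annotation)
top = rows[0]
print(f"top term: {top.term_id} ({top.category}), k={top.k}/K={top.K}, "
      f"p={top.p:.2e}, q={top.q:.2e}")
```

prints

```
73/140 compounds pass the screen
236 targets, 854 disease genes, 193 intersection genes, 73 effective compounds
core: 14 nodes (planted 23); Jaccard with planted core = 0.61
top term: T0001 (KEGG), k=12/K=20, p=7.46e-21, q=7.46e-20
```

Half the compounds survive the pharmacokinetic screen (the generator draws
them that way); the two-step median filter shrinks the 150-node network to a
14-node core that overlaps the planted 23-node dense block (Jaccard 0.61 —
the filter keeps only nodes above *all six* medians, so it recovers the
densest part of the planted block); and the planted KEGG term tops the
enrichment table by ~19 orders of magnitude.

The same analysis is available from the shell:

```sh
netpharm simulate --out-dir inputs --seed 7
netpharm screen --compounds inputs/compounds.tsv --associations inputs/associations.tsv --out-prefix out/screened
netpharm core-extract --edges inputs/ppi_edges.tsv --steps 2 --out-dir out/core
netpharm run-all --config config.yaml   # everything, from a flat YAML config
```

Every run is deterministic given its config and seed: stage outputs are
sorted TSV/SIF/GraphML files and the JSON report carries the counts,
parameter echo and content hashes needed to audit a run.

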