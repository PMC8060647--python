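# Methods

## Scope and model

The package implements the computational stages of a network-pharmacology
target-identification study for a multi-herb formula: pharmacokinetic
screening of candidate ingredients, set-algebraic identification of
candidate therapeutic targets, construction of a herb–compound–target
network, extraction of a topological core from a protein–protein interaction
(PPI) graph, and over-representation analysis of the core genes. The
underlying modelling assumptions are those of the field: catalogued
compound→target associations are taken at face value; a PPI subnetwork
exported for the candidate genes is treated as the primary network *as
supplied* (its construction — database, species, confidence cutoff — is the
upstream tool's responsibility, so the package never recomputes it and never
thresholds edge confidence unless explicitly asked via `min_confidence`);
and "importance" of a gene is operationalized purely topologically.

## Compound screen

A record passes when `OB ≥ ob_min` and (`DL ≥ dl_min` or
`score ≥ score_min`). Defaults: `ob_min = 30` (percent), `dl_min = 0.18`
(unitless, the conventional drug-likeness cutoff), `score_min = 20`
(database score, unitless). All three comparisons are inclusive — the
thresholds are printed as closed inequalities wherever this screen is used —
and the DL/score disjunction is applied per record regardless of which
source database produced it, since ingredient tables routinely mix sources
that supply only one of the two attributes. A record with no score can only
pass through DL. Screening is idempotent and monotone in every threshold.

The dose utility implements the body-surface-area conversion
`DB(rat) = DA(human) · 7/388` for a 70 kg adult; units follow the input
(g/day in → g/kg/day out).

## Gene-set stages

Disease sources are combined by plain union — no voting or per-source score
cutoff — with per-gene provenance retained for reporting. Gene symbols are
normalized (trim, collapse internal whitespace, uppercase) at every file
boundary; alias resolution is deliberately out of scope, as it requires an
external service, but a pre-normalized alias-remapped list can be supplied
in place of any input. The candidate-target set is the exact intersection
of drug targets and disease genes; effective compounds are the screened
compounds with at least one association into it.

## Six-metric hub extraction

Definitions (all on a simple undirected graph, computed per connected
component where relevant):

* `DC(v)` — degree.
* `BC(v) = Σ_{s<t, s≠v≠t} σ_st(v)/σ_st` — betweenness over unordered pairs,
  unnormalized. Any fixed normalization is a strictly increasing transform
  and cannot change the filter's outcome (rank invariance, tested).
* `CC(v) = |R(v)| / Σ_{u∈R(v)} d(v,u)` with `R(v)` the nodes reachable from
  `v`; 0 for an isolated node. This reachable-set form is well defined on
  disconnected graphs, which exported PPI subnetworks frequently are.
* `EC` — the nonnegative leading eigenvector of the adjacency matrix,
  computed per component and unit-normalized (Euclidean) within the
  component; a singleton component gets 1.
* `LAC(v) = 2·e(N(v))/|N(v)|` — mean within-neighbourhood degree.
* `NC(v) = Σ_{u∈N(v)} ECC(u,v)`, `ECC(u,v) = z_uv / min(deg u−1, deg v−1)`
  with `z_uv` the number of common neighbours and ECC defined as 0 when the
  denominator is not positive.

DC, BC and CC are evaluated through networkx (whose unnormalized
betweenness and non-Wasserman–Faust closeness are exactly these
definitions); EC, LAC and NC are implemented here. The test suite checks
all six against independent naive implementations (σ-product betweenness,
dense symmetric eigendecomposition, direct neighbourhood counting) on every
non-isomorphic connected graph with ≤ 7 nodes and on 200 random graphs with
≤ 30 nodes, at 1e-9.

**Filtering rule.** One step keeps exactly the nodes *strictly* greater
than the median in **all six** metrics (even node count: median = mean of
the two middle order statistics) and induces the subgraph on them. Strict
exceedance guarantees shrinkage and makes vertex-transitive graphs (e.g.
complete graphs) filter to nothing; ties *at* the median are excluded.
Medians are recomputed on each step's subgraph — the screen is a procedure
on the current network, not a fixed cutoff. Default `steps = 2`. If a step
would empty the graph the iteration stops early, keeps the last nonempty
subgraph as the core, and flags the result as truncated rather than
erroring: the flag preserves auditability while keeping the operation
total.

**Numerical choice (EC).** The power iteration runs on `A + I`: the shift
leaves eigenvectors unchanged but breaks the ±λ symmetry of bipartite
components, guaranteeing convergence to the Perron vector from a uniform
positive start. The stopping rule is a successive-iterate sup-norm
difference below 1e-12 (max 10,000 iterations): with spectral ratio `r`
the true eigenvector error is roughly `diff/(1−r)`, and 1e-12 keeps the
vector accurate to ~1e-9 even on slowly mixing graphs such as 30-node paths
(`r ≈ 0.992`).

## Tripartite network

Compound–target edges are restricted to intersection genes; each retained
compound links to its herb; nodes with no surviving edge are absent. Node
labels must be unique across layers (the synthetic schema guarantees this;
real inputs where a compound id collides with a gene symbol are rejected).
Compound ranking is by number of distinct targets hit, ties broken
lexicographically by compound name so the ranking is stable across runs.
Exports: SIF (`pp` for PPI, `hc`/`ct` for typed tripartite edges; isolated
nodes as single-token lines), GraphML, and edge TSV; re-import reproduces
node and edge sets exactly.

## Enrichment

Exact one-sided hypergeometric upper tail `P(X ≥ k)` for
`X ~ Hypergeometric(N, K, n)`, evaluated through scipy's survival function
(log-space internally) and verified against integer enumeration for all
margins with `N ≤ 30` at 1e-12. Only terms hit at least once are tested, so
the BH family size per category is the number of tested terms in that
category. BH adjustment runs within each category (BP/CC/MF/KEGG) by
default — mirroring per-ontology enrichment tooling — with
`per_category_fdr=False` for a single global family. The universe defaults
to all annotated genes unless an explicit universe is supplied; query genes
outside the universe are dropped with a warning. Significance default
`q_max = 0.05`; reporting defaults top-10 per GO category and top-30 KEGG,
ties at the cut broken by ascending p then term id.

Because the test is exact and the counts discrete, its achieved size is
*conservative*: under a null query the fraction of terms reaching p ≤ 0.05
is somewhat below 0.05 (≈ 0.033 at the simulation margins used in the
tests: universe 1000, query 150, term sizes 20–60). The calibration test
asserts the fraction stays within two binomial standard errors of 0.05 over
200 simulations, which the conservative exact test satisfies; it can never
be anticonservative.

## Synthetic data: what it does and does not emulate

The generators reproduce the *structure* the analysis relies on, not the
content of any real database:

* compound tables with 20% of each attribute's mass within ±5% of its
  threshold (OB on 0–100, DL on [0,1], score on [0,40]; ~30% of records
  score-free), so inclusive-boundary handling is exercised;
* disease sources sharing a common pool of `round(overlap·size)` genes;
* a planted-core PPI graph — Erdős–Rényi background at `p_bg` with a
  `core_size` block rewired at `p_core` — whose default
  (n=150, core=23, p_core=0.8, p_bg=0.05) mirrors the scale of a published
  seven-herb analysis (150-node primary network, 23-node core) and gives
  hub extraction a measurable ground truth;
* an annotation map whose planted term draws a fraction
  `enrichment_strength` of its members from a designated target set.

Defaults: 7 herbs × 20 ingredients at `frac_pass = 0.5`; 7 disease sources
of 300 genes at overlap 0.3 over a 1,000-symbol universe; 120 terms across
the four categories with a 20-gene planted term at strength 0.9. Symbols
are synthetic tokens (`G0001`, …) so no biological claim is implied.

Not emulated: real database schema dialects, STRING confidence-score
distributions, degree heterogeneity of real interactomes (scale-free tails,
study bias), GO term nesting/propagation, or correlated term memberships.
Passing tests therefore demonstrate correctness of the *procedure* and
recoverability of planted structure under the stated conditions — not that
any particular biological conclusion from real data is right.

## Determinism

Every generator consumes one explicit integer seed through its own
`numpy.random.Generator`; no global state. All writers sort rows, so equal
objects produce byte-identical files. The pipeline report contains stage
counts, the effective parameter echo, truncation flags and sha256 hashes of
every output file — and deliberately no wall-clock values, so that rerunning
an identical config on identical inputs yields a bit-identical report;
timestamps appear only on the log stream.

## Known limitations

* Hub extraction on very small or highly symmetric graphs truncates
  immediately (by design); the truncation flag must be checked.
* The reachable-set closeness is one convention among several for
  disconnected graphs; results on fragmented networks depend on it.
* Label-permutation calibration covers the test statistic, not annotation
  correlation; real GO terms are strongly nested and the per-category BH
  families correspondingly dependent.
* No identifier mapping between gene namespaces and no alias resolution;
  inputs must share one symbol namespace.
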