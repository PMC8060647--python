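"""Synthetic input generators for the whole pipeline.

Real network-pharmacology studies pull their inputs from pharmacology
databases (herb-ingredient tables with OB/DL/score attributes), disease-gene
databases, a PPI server and GO/KEGG annotation services. None of those can be
assumed reachable or stable, so this module generates inputs with the
statistical structure the downstream analysis relies on:

* multi-herb compound tables whose OB/DL/score values deliberately straddle
  the screening thresholds (OB >= 30, DL >= 0.18, score >= 20), so boundary
  semantics are exercised;
* several overlapping disease-gene sources;
* a PPI graph with a planted dense core (an Erdos-Renyi background at density
  ``p_bg`` with a ``core_size`` block rewired at density ``p_core``), giving
  hub extraction a known ground truth;
* an annotation map with one planted over-represented term.

Gene symbols are synthetic tokens ("G0001", ...) so no real gene identity is
implied. Every generator takes an explicit integer seed and draws from its
own `numpy` Generator; no global random state is touched, and the same
arguments always reproduce the same output bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from . import io
from .records import AnnotationMap, AnnotationTerm, CompoundRecord, GeneSet, TargetAssociation

__all__ = [
    "SyntheticBundle",
    "gen_universe",
    "gen_compound_table",
    "gen_associations",
    "gen_disease_sources",
    "gen_ppi_planted_core",
    "gen_annotation_map",
    "gen_bundle",
    "write_bundle",
    "PAPER_SCALE",
]

# Screening thresholds the generated values straddle (same defaults as
# netpharm.screen.screen_compounds).
OB_MIN = 30.0
DL_MIN = 0.18
SCORE_MIN = 20.0

# Fraction of draws placed within +/-5% of the relevant threshold.
_BOUNDARY_MASS = 0.2
_BOUNDARY_BAND = 0.05

#: Generator preset mirroring the scale of a published seven-herb analysis:
#: a 150-node primary PPI network with a 23-node dense core.
PAPER_SCALE = dict(
    n_genes=1000,
    n_herbs=7,
    per_herb=20,
    frac_pass=0.5,
    n_sources=7,
    source_size=300,
    source_overlap=0.3,
    n_nodes=150,
    core_size=23,
    p_core=0.8,
    p_bg=0.05,
    n_terms=120,
    planted_term_size=20,
    enrichment_strength=0.9,
)


@dataclass(frozen=True)
class SyntheticBundle:
    """All pipeline inputs generated from one seed, plus the planted truths."""

    compound_table: tuple[CompoundRecord, ...]
    associations: tuple[TargetAssociation, ...]
    disease_sources: dict[str, GeneSet]
    ppi: nx.Graph
    planted_core: frozenset[str]
    annotation: AnnotationMap
    planted_term: str
    universe: GeneSet
    seed: int


def gen_universe(n_genes: int) -> GeneSet:
    """Synthetic symbol universe G0001 ... G<n>."""
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    return GeneSet.from_symbols(
        "universe", (f"G{i:04d}" for i in range(1, n_genes + 1)), provenance=("synthetic",)
    )


def _draw(rng: np.random.Generator, lo: float, hi: float, thr: float, passing: bool) -> float:
    """Draw one value on the passing (>= thr) or failing (< thr) side.

    A fixed fraction of the mass is concentrated within +/-5% of the
    threshold so that inclusive-boundary handling downstream is exercised.
    """
    if passing:
        lo_r, hi_r = thr, hi
        band_hi = min(hi, thr * (1 + _BOUNDARY_BAND))
        band = (thr, band_hi)
    else:
        lo_r, hi_r = lo, thr
        band_lo = max(lo, thr * (1 - _BOUNDARY_BAND))
        band = (band_lo, thr)
    if rng.random() < _BOUNDARY_MASS and band[1] > band[0]:
        return float(rng.uniform(*band))
    return float(rng.uniform(lo_r, hi_r))


def gen_compound_table(
    n_herbs: int, per_herb: int, frac_pass: float, seed: int
) -> list[CompoundRecord]:
    """Generate ``n_herbs * per_herb`` compound records.

    Each record independently passes the pharmacokinetic screen
    (OB >= 30 AND (DL >= 0.18 OR score >= 20)) with probability
    ``frac_pass``; a random ~30% of records carry no database score and are
    judged on DL alone, as happens when a source database supplies no score.
    """
    if n_herbs < 1 or per_herb < 1:
        raise ValueError("n_herbs and per_herb must be positive")
    if not 0.0 <= frac_pass <= 1.0:
        raise ValueError(f"frac_pass must lie in [0, 1], got {frac_pass!r}")
    rng = np.random.default_rng(seed)
    records: list[CompoundRecord] = []
    k = 0
    for h in range(1, n_herbs + 1):
        herb = f"herb{h:02d}"
        for _ in range(per_herb):
            k += 1
            cid = f"C{k:04d}"
            passes = rng.random() < frac_pass
            has_score = rng.random() < 0.7
            if passes:
                ob = _draw(rng, 0.0, 100.0, OB_MIN, passing=True)
                if not has_score:
                    dl, score = _draw(rng, 0.0, 1.0, DL_MIN, True), None
                else:
                    mode = rng.integers(3)  # dl-only, score-only, both
                    dl = _draw(rng, 0.0, 1.0, DL_MIN, mode != 1)
                    score = _draw(rng, 0.0, 40.0, SCORE_MIN, mode != 0)
            else:
                ob_fails = rng.random() < 0.5
                ob = _draw(rng, 0.0, 100.0, OB_MIN, passing=not ob_fails)
                if ob_fails:
                    dl = float(rng.uniform(0.0, 1.0))
                    score = float(rng.uniform(0.0, 40.0)) if has_score else None
                else:
                    dl = _draw(rng, 0.0, 1.0, DL_MIN, False)
                    score = _draw(rng, 0.0, 40.0, SCORE_MIN, False) if has_score else None
            records.append(
                CompoundRecord(
                    compound_id=cid,
                    herb=herb,
                    name=f"cmpd-{cid.lower()}",
                    OB=round(ob, 4),
                    DL=round(min(dl, 1.0), 4),
                    score=None if score is None else round(score, 4),
                )
            )
    return records


def gen_associations(
    compounds: Sequence[CompoundRecord],
    universe: GeneSet,
    seed: int,
    targets_per_compound: tuple[int, int] = (2, 8),
    focus: Optional[Sequence[str]] = None,
    focus_prob: float = 0.6,
) -> list[TargetAssociation]:
    """Compound->gene association pairs.

    Each compound receives a uniform number of distinct targets in
    ``targets_per_compound``; when ``focus`` nodes are given (typically the
    PPI node set), each target is drawn from them with probability
    ``focus_prob``, which concentrates targets on network genes the way real
    drug-target catalogues concentrate on well-studied proteins.
    """
    if not compounds:
        raise ValueError("compounds must be nonempty")
    lo, hi = targets_per_compound
    if lo < 1 or hi < lo:
        raise ValueError("targets_per_compound must be a valid positive range")
    rng = np.random.default_rng(seed)
    uni = sorted(universe.genes)
    foc = sorted(focus) if focus else None
    pairs: set[tuple[str, str]] = set()
    for c in compounds:
        m = int(rng.integers(lo, hi + 1))
        chosen: set[str] = set()
        while len(chosen) < m:
            pool = foc if (foc and rng.random() < focus_prob) else uni
            chosen.add(pool[int(rng.integers(len(pool)))])
        pairs.update((c.compound_id, g) for g in chosen)
    return [TargetAssociation(cid, g) for cid, g in sorted(pairs)]


def gen_disease_sources(
    universe: GeneSet, n_sources: int, size_each: int, overlap: float, seed: int
) -> dict[str, GeneSet]:
    """Named disease-gene sources with controlled pairwise overlap.

    A shared pool of ``round(overlap * size_each)`` genes is common to every
    source; the remainder of each source is drawn from the rest of the
    universe — disjointly across sources when the universe is large enough,
    otherwise independently.
    """
    if n_sources < 1 or size_each < 1:
        raise ValueError("n_sources and size_each must be positive")
    if size_each > len(universe):
        raise ValueError(f"size_each={size_each} exceeds universe size {len(universe)}")
    if not 0.0 <= overlap <= 1.0:
        raise ValueError(f"overlap must lie in [0, 1], got {overlap!r}")
    rng = np.random.default_rng(seed)
    uni = np.array(sorted(universe.genes))
    n_shared = int(round(overlap * size_each))
    shared_idx = rng.choice(len(uni), size=n_shared, replace=False)
    shared = set(uni[shared_idx])
    rest = np.array(sorted(set(uni) - shared))
    need = size_each - n_shared
    sources: dict[str, GeneSet] = {}
    disjoint = n_sources * need <= len(rest)
    if disjoint and need > 0:
        perm = rng.permutation(len(rest))
    for s in range(n_sources):
        name = f"source{s + 1:02d}"
        if need == 0:
            own: set[str] = set()
        elif disjoint:
            own = set(rest[perm[s * need : (s + 1) * need]])
        else:
            own = set(rest[rng.choice(len(rest), size=need, replace=False)])
        sources[name] = GeneSet(name=name, genes=frozenset(shared | own), provenance=(name,))
    return sources


def gen_ppi_planted_core(
    n_nodes: int,
    core_size: int,
    p_core: float,
    p_bg: float,
    seed: int,
    nodes: Optional[Sequence[str]] = None,
) -> tuple[nx.Graph, frozenset[str]]:
    """Simple undirected graph with a planted dense block.

    Background pairs are wired independently at density ``p_bg``; pairs
    within a randomly chosen ``core_size`` block at density ``p_core``.
    Requires ``p_core > p_bg`` — otherwise the planted structure is
    unrecoverable by construction. Each edge carries a uniform confidence in
    [0.4, 1.0].
    """
    if n_nodes < 1 or core_size < 1:
        raise ValueError("n_nodes and core_size must be positive")
    if core_size > n_nodes:
        raise ValueError("core_size cannot exceed n_nodes")
    for name, p in (("p_core", p_core), ("p_bg", p_bg)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p!r}")
    if p_core <= p_bg:
        raise ValueError("p_core must exceed p_bg (planted core must be denser)")
    rng = np.random.default_rng(seed)
    if nodes is None:
        labels = [f"G{i:04d}" for i in range(1, n_nodes + 1)]
    else:
        labels = sorted(nodes)
        if len(labels) != n_nodes:
            raise ValueError("len(nodes) must equal n_nodes")
    core = frozenset(np.array(labels)[rng.choice(n_nodes, size=core_size, replace=False)])
    g = nx.Graph()
    g.add_nodes_from(labels)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            a, b = labels[i], labels[j]
            p = p_core if (a in core and b in core) else p_bg
            if rng.random() < p:
                g.add_edge(a, b, confidence=round(float(rng.uniform(0.4, 1.0)), 3))
    return g, core


def gen_annotation_map(
    universe: GeneSet,
    n_terms: int,
    planted_term_size: int,
    target_set: GeneSet,
    enrichment_strength: float,
    seed: int,
    term_size_range: tuple[int, int] = (10, 50),
) -> tuple[AnnotationMap, str]:
    """Annotation map with one planted over-represented term.

    The planted term (always ``T0001``, category KEGG) draws a fraction
    ``enrichment_strength`` of its members from ``target_set`` and the rest
    from the remaining universe; all other terms are uniform draws. Every
    term carries a category from {BP, CC, MF, KEGG}.
    """
    if len(universe) == 0:
        raise ValueError("universe must be nonempty")
    if n_terms < 1 or planted_term_size < 1:
        raise ValueError("n_terms and planted_term_size must be positive")
    if planted_term_size > len(universe):
        raise ValueError("planted_term_size exceeds universe size")
    if not 0.0 <= enrichment_strength <= 1.0:
        raise ValueError("enrichment_strength must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    uni = np.array(sorted(universe.genes))
    target = np.array(sorted(target_set.genes & universe.genes))
    n_from_target = min(int(round(enrichment_strength * planted_term_size)), len(target))
    chosen = set(target[rng.choice(len(target), size=n_from_target, replace=False)])
    rest_pool = np.array(sorted(set(uni) - chosen))
    n_rest = planted_term_size - n_from_target
    if n_rest > 0:
        chosen |= set(rest_pool[rng.choice(len(rest_pool), size=n_rest, replace=False)])
    amap = AnnotationMap()
    planted_id = "T0001"
    amap.add(
        AnnotationTerm(
            term_id=planted_id,
            term_name="planted-term",
            category="KEGG",
            genes=frozenset(chosen),
        )
    )
    lo, hi = term_size_range
    cats = AnnotationTerm.CATEGORIES
    for t in range(2, n_terms + 1):
        size = int(rng.integers(lo, min(hi, len(uni)) + 1))
        genes = frozenset(uni[rng.choice(len(uni), size=size, replace=False)])
        amap.add(
            AnnotationTerm(
                term_id=f"T{t:04d}",
                term_name=f"term-{t:04d}",
                category=cats[int(rng.integers(len(cats)))],
                genes=genes,
            )
        )
    return amap, planted_id


def gen_bundle(seed: int, **overrides) -> SyntheticBundle:
    """Generate every pipeline input coherently from one seed.

    Defaults follow :data:`PAPER_SCALE`; keyword overrides replace individual
    parameters. Child seeds for each generator are drawn from one parent
    stream, so the bundle is reproducible bit-for-bit from ``seed`` alone.
    """
    params = dict(PAPER_SCALE)
    unknown = set(overrides) - set(params)
    if unknown:
        raise ValueError(f"unknown generator parameters: {sorted(unknown)}")
    params.update(overrides)

    parent = np.random.default_rng(seed)
    child = lambda: int(parent.integers(0, 2**31 - 1))  # noqa: E731

    universe = gen_universe(params["n_genes"])
    compounds = gen_compound_table(
        params["n_herbs"], params["per_herb"], params["frac_pass"], child()
    )
    node_rng = np.random.default_rng(child())
    ppi_nodes = sorted(
        np.array(sorted(universe.genes))[
            node_rng.choice(len(universe), size=params["n_nodes"], replace=False)
        ]
    )
    ppi, core = gen_ppi_planted_core(
        params["n_nodes"],
        params["core_size"],
        params["p_core"],
        params["p_bg"],
        child(),
        nodes=ppi_nodes,
    )
    associations = gen_associations(
        compounds, universe, child(), focus=sorted(ppi.nodes), focus_prob=0.6
    )
    sources = gen_disease_sources(
        universe,
        params["n_sources"],
        params["source_size"],
        params["source_overlap"],
        child(),
    )
    annotation, planted_term = gen_annotation_map(
        universe,
        params["n_terms"],
        params["planted_term_size"],
        GeneSet(name="planted-core", genes=core),
        params["enrichment_strength"],
        child(),
    )
    return SyntheticBundle(
        compound_table=tuple(compounds),
        associations=tuple(associations),
        disease_sources=sources,
        ppi=ppi,
        planted_core=core,
        annotation=annotation,
        planted_term=planted_term,
        universe=universe,
        seed=seed,
    )


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, Path]:
    """Materialize a bundle in the pipeline's input schemas; returns file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["compounds"] = outdir / "compounds.tsv"
    io.write_compound_tsv(bundle.compound_table, paths["compounds"])
    paths["associations"] = outdir / "associations.tsv"
    io.write_association_tsv(bundle.associations, paths["associations"])
    for name, gs in sorted(bundle.disease_sources.items()):
        p = outdir / f"disease_{name}.txt"
        io.write_gene_list(gs, p)
        paths[f"disease:{name}"] = p
    paths["ppi_edges"] = outdir / "ppi_edges.tsv"
    io.write_edge_tsv(
        [(a, b, d.get("confidence", 1.0)) for a, b, d in bundle.ppi.edges(data=True)],
        paths["ppi_edges"],
    )
    paths["annotation"] = outdir / "annotation.tsv"
    io.write_annotation_tsv(bundle.annotation, paths["annotation"])
    paths["universe"] = outdir / "universe.txt"
    io.write_gene_list(bundle.universe, paths["universe"])
    paths["planted_core"] = outdir / "planted_core.txt"
    io.write_gene_list(sorted(bundle.planted_core), paths["planted_core"])
    return paths
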