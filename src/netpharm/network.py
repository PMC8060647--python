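"""Graph construction, six-metric topological scoring, and hub extraction.

The hub-extraction procedure scores every node of a PPI graph on six
centralities —

* **DC** degree;
* **BC** betweenness, unnormalized, accumulated over unordered pairs;
* **CC** closeness in the reachable-set form ``|R(v)| / sum of d(v, u)``
  (0 for an isolated node), which is well defined on disconnected graphs;
* **EC** eigenvector centrality: the nonnegative leading eigenvector of the
  adjacency matrix, computed per connected component and unit-normalized
  (Euclidean) within the component;
* **LAC** local average connectivity: the average degree of v's neighbours
  within the subgraph induced on the neighbourhood, ``2 e(N(v)) / |N(v)|``;
* **NC** the sum over incident edges of the edge clustering coefficient
  ``ECC(u, v) = z_uv / min(deg u - 1, deg v - 1)``, where ``z_uv`` counts
  common neighbours (0 whenever the denominator is not positive)

— then keeps the nodes strictly above the median in *all six* metrics and
recurses on the induced subgraph. Two rounds of this above-median filter
("two-step screening") shrink a primary PPI network to its dense core. The
filter is rank-based, so any strictly increasing per-metric rescaling leaves
the surviving node set unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd

from .records import CompoundRecord, GeneSet, TargetAssociation

__all__ = [
    "build_ppi",
    "compute_centralities",
    "median_filter_step",
    "extract_core",
    "CoreStep",
    "CoreExtractionResult",
    "build_tripartite",
    "rank_compounds_by_degree",
    "export_network",
    "read_sif",
]

METRICS = ("DC", "BC", "CC", "EC", "LAC", "NC")

# Successive-iterate stop for the EC power iteration. The true eigenvector
# error is roughly diff/(1-r) for spectral ratio r, so stopping at 1e-12
# keeps the vector accurate to ~1e-9 even on slowly mixing graphs (long
# paths/cycles, r ~ 0.992).
_EC_TOL = 1e-12
_EC_MAX_ITER = 10_000


def build_ppi(
    edges: Iterable[tuple[str, str, float]] | Iterable[tuple[str, str]],
    min_confidence: float | None = None,
) -> nx.Graph:
    """Simple undirected graph from an edge list; self-loops are dropped.

    ``min_confidence`` optionally discards edges below a confidence cutoff
    (off by default: confidence is carried through, never thresholded unless
    asked).
    """
    g = nx.Graph()
    for e in edges:
        a, b = e[0], e[1]
        if a == b:
            continue
        conf = float(e[2]) if len(e) > 2 else 1.0
        if min_confidence is not None and conf < min_confidence:
            continue
        g.add_edge(a, b, confidence=conf)
    return g


def compute_centralities(graph: nx.Graph) -> pd.DataFrame:
    """Per-node table of the six metrics, indexed by node in sorted order."""
    if graph.number_of_nodes() == 0:
        raise ValueError("graph must be nonempty")
    nodes = sorted(graph.nodes)
    adj = {v: set(graph.adj[v]) for v in nodes}
    deg = {v: len(adj[v]) for v in nodes}

    bc = nx.betweenness_centrality(graph, normalized=False)
    cc = nx.closeness_centrality(graph, wf_improved=False)
    ec = _eigenvector_per_component(graph)

    lac = {}
    nc = {}
    for v in nodes:
        nbrs = adj[v]
        if not nbrs:
            lac[v] = 0.0
            nc[v] = 0.0
            continue
        # edges within the induced neighbourhood, each counted twice
        e2 = sum(len(adj[u] & nbrs) for u in nbrs)
        lac[v] = e2 / len(nbrs)
        total = 0.0
        for u in nbrs:
            denom = min(deg[u] - 1, deg[v] - 1)
            if denom > 0:
                total += len(adj[u] & nbrs) / denom
        nc[v] = total

    return pd.DataFrame(
        {
            "DC": [float(deg[v]) for v in nodes],
            "BC": [bc[v] for v in nodes],
            "CC": [cc[v] for v in nodes],
            "EC": [ec[v] for v in nodes],
            "LAC": [lac[v] for v in nodes],
            "NC": [nc[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


def _eigenvector_per_component(graph: nx.Graph) -> dict[str, float]:
    """Nonnegative leading adjacency eigenvector, unit 2-norm per component.

    Power iteration on A + I (the shift leaves eigenvectors unchanged but
    breaks the +/-lambda symmetry of bipartite components, guaranteeing
    convergence to the Perron vector). A singleton component gets EC = 1.
    """
    out: dict[str, float] = {}
    for comp in nx.connected_components(graph):
        comp_nodes = sorted(comp)
        n = len(comp_nodes)
        if n == 1:
            out[comp_nodes[0]] = 1.0
            continue
        a = nx.to_numpy_array(graph, nodelist=comp_nodes, dtype=float)
        np.fill_diagonal(a, 1.0)  # shift A -> A + I
        v = np.full(n, 1.0 / np.sqrt(n))
        for _ in range(_EC_MAX_ITER):
            w = a @ v
            w /= np.linalg.norm(w)
            if np.max(np.abs(w - v)) < _EC_TOL:
                v = w
                break
            v = w
        v = np.abs(v)
        v /= np.linalg.norm(v)
        out.update(zip(comp_nodes, v.tolist()))
    return out


def median_filter_step(graph: nx.Graph, table: pd.DataFrame) -> nx.Graph:
    """Induced subgraph on the nodes strictly above the median in all six metrics.

    Medians are taken over the current node set (even count: mean of the two
    middle order statistics). An empty result is legal — e.g. on any
    vertex-transitive graph no node strictly exceeds the median.
    """
    if set(table.index) != set(graph.nodes):
        raise ValueError("centrality table does not match the graph's node set")
    medians = table[list(METRICS)].median()
    mask = (table[list(METRICS)] > medians).all(axis=1)
    keep = sorted(table.index[mask])
    return graph.subgraph(keep).copy()


@dataclass(frozen=True)
class CoreStep:
    """One filtering round: the medians applied and the surviving subgraph."""

    medians: dict[str, float]
    table: pd.DataFrame
    graph: nx.Graph

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)


@dataclass(frozen=True)
class CoreExtractionResult:
    """Outcome of iterated above-median filtering.

    ``steps[i].graph`` is the subgraph surviving round i+1; node sets form a
    descending chain from the primary graph. ``truncated`` flags an early
    stop: a round would have emptied the graph, so the last nonempty
    subgraph was kept as the core.
    """

    primary: nx.Graph
    steps: tuple[CoreStep, ...] = field(default_factory=tuple)
    truncated: bool = False

    @property
    def core(self) -> nx.Graph:
        return self.steps[-1].graph if self.steps else self.primary


def extract_core(graph: nx.Graph, steps: int = 2) -> CoreExtractionResult:
    """Iterate centrality scoring + strict-median filtering ``steps`` times.

    Centralities and medians are recomputed on each round's induced
    subgraph. If a round would empty the graph the iteration stops early and
    the result is flagged truncated.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if graph.number_of_nodes() == 0:
        raise ValueError("graph must be nonempty")
    done: list[CoreStep] = []
    current = graph
    truncated = False
    for _ in range(steps):
        table = compute_centralities(current)
        nxt = median_filter_step(current, table)
        if nxt.number_of_nodes() == 0:
            truncated = True
            break
        done.append(
            CoreStep(
                medians={m: float(table[m].median()) for m in METRICS},
                table=table,
                graph=nxt,
            )
        )
        current = nxt
    return CoreExtractionResult(primary=graph, steps=tuple(done), truncated=truncated)


def build_tripartite(
    screened: Sequence[CompoundRecord],
    associations: Iterable[TargetAssociation],
    intersection: GeneSet,
) -> nx.Graph:
    """Herb–compound–target network restricted to intersection genes.

    Node attribute ``layer`` is one of herb/compound/target; edges carry
    ``kind`` = ``hc`` (herb–compound) or ``ct`` (compound–target). A compound
    whose associations all fall outside the intersection is absent, as is any
    herb left without compounds; no node has zero edges. Node labels must be
    unique across layers (herb names, compound ids and gene symbols may not
    collide).
    """
    by_compound: dict[str, set[str]] = {}
    for a in associations:
        if a.gene in intersection.genes:
            by_compound.setdefault(a.compound_id, set()).add(a.gene)
    g = nx.Graph()
    for r in screened:
        targets = by_compound.get(r.compound_id)
        if not targets:
            continue
        g.add_node(r.herb, layer="herb")
        g.add_node(r.compound_id, layer="compound", name=r.name)
        g.add_edge(r.herb, r.compound_id, kind="hc")
        for t in sorted(targets):
            g.add_node(t, layer="target")
            g.add_edge(r.compound_id, t, kind="ct")
    layers = nx.get_node_attributes(g, "layer")
    if len(layers) != g.number_of_nodes():
        raise ValueError("node labels collide across layers")
    return g


def rank_compounds_by_degree(net: nx.Graph, k: int = 10) -> list[str]:
    """Top-k compound ids by number of distinct targets hit.

    Ties are broken lexicographically by compound name (falling back to the
    id), which makes the ranking deterministic across runs.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if net.number_of_nodes() == 0:
        raise ValueError("network must be nonempty")
    layers = nx.get_node_attributes(net, "layer")
    rows = []
    for v, layer in layers.items():
        if layer != "compound":
            continue
        tdeg = sum(1 for u in net.adj[v] if layers.get(u) == "target")
        rows.append((-tdeg, net.nodes[v].get("name", v), v))
    rows.sort()
    return [v for _, _, v in rows[:k]]


# --- export / import -------------------------------------------------------

PathLike = Union[str, Path]


def export_network(graph: nx.Graph, fmt: str, path: PathLike) -> None:
    """Write a graph as SIF, GraphML or an edge TSV.

    SIF interaction types: ``pp`` for PPI edges, ``hc``/``ct`` for typed
    tripartite edges (taken from the edge ``kind`` attribute); isolated
    nodes become single-token lines. Re-importing reproduces the node and
    edge sets exactly.
    """
    fmt = fmt.lower()
    path = Path(path)
    if fmt == "sif":
        lines = []
        for a, b, d in sorted(graph.edges(data=True)):
            if a > b:
                a, b = b, a
            lines.append(f"{a}\t{d.get('kind', 'pp')}\t{b}")
        for v in sorted(graph.nodes):
            if graph.degree(v) == 0:
                lines.append(str(v))
        path.write_text("".join(ln + "\n" for ln in sorted(lines)), encoding="utf-8")
    elif fmt == "graphml":
        nx.write_graphml(graph, path, named_key_ids=True)
    elif fmt in ("tsv", "edge-tsv"):
        rows = []
        for a, b, d in graph.edges(data=True):
            if a > b:
                a, b = b, a
            rows.append((a, b, d.get("kind", "pp"), d.get("confidence", "")))
        df = pd.DataFrame(
            sorted(rows), columns=["source", "target", "interaction", "confidence"]
        )
        df.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown export format {fmt!r} (use sif, graphml or tsv)")


def read_sif(path: PathLike) -> nx.Graph:
    """Parse a SIF file back into a graph (edge ``kind`` preserved)."""
    g = nx.Graph()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        parts = line.split("\t")
        if len(parts) == 1 and parts[0]:
            g.add_node(parts[0])
        elif len(parts) >= 3:
            g.add_edge(parts[0], parts[2], kind=parts[1])
    return g


def write_centrality_tsv(table: pd.DataFrame, path: PathLike) -> None:
    """Write a per-node centrality table (node + the six metric columns)."""
    table.sort_index().to_csv(path, sep="\t", lineterminator="\n", encoding="utf-8")
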