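"""End-to-end orchestration: screen -> merge -> intersect -> network -> core -> enrichment.

A run is driven by a :class:`PipelineConfig` (flat key-value document,
YAML-loadable; CLI flags override file keys) and produces stage output files
plus a machine-readable :class:`RunReport`. Reports contain stage counts, the
effective parameter set, truncation flags and content hashes of every output
file — but no wall-clock values, so a rerun with identical config and inputs
is bit-identical. Timestamps appear only on the log stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from . import io, synthetic
from .enrichment import enrich, rows_to_frame, select_top
from .genesets import effective_compounds, intersect_targets, merge_sources
from .network import (
    build_ppi,
    build_tripartite,
    export_network,
    extract_core,
    rank_compounds_by_degree,
    write_centrality_tsv,
)
from .records import GeneSet
from .screen import collect_targets, screen_compounds

__all__ = ["PipelineConfig", "RunReport", "PipelineError", "run_pipeline", "simulate"]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class PipelineError(RuntimeError):
    """A stage precondition failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Input paths, thresholds and the output directory for one run."""

    compounds: Path
    associations: Path
    disease_sources: tuple[Path, ...]
    ppi_edges: Path
    annotation: Path
    outdir: Path
    universe: Optional[Path] = None
    ob_min: float = 30.0
    dl_min: float = 0.18
    score_min: float = 20.0
    min_confidence: Optional[float] = None
    steps: int = 2
    q_max: float = 0.05
    top_go: int = 10
    top_kegg: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        self.compounds = Path(self.compounds)
        self.associations = Path(self.associations)
        self.disease_sources = tuple(Path(p) for p in self.disease_sources)
        self.ppi_edges = Path(self.ppi_edges)
        self.annotation = Path(self.annotation)
        self.outdir = Path(self.outdir)
        if self.universe is not None:
            self.universe = Path(self.universe)
        if not 0 < self.q_max <= 1:
            raise ValueError("q_max must lie in (0, 1]")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.top_go < 1 or self.top_kegg < 1:
            raise ValueError("top-N limits must be positive")

    @classmethod
    def from_yaml(cls, path: PathLike, **overrides) -> "PipelineConfig":
        """Load a flat key-value config; keyword overrides take precedence."""
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return {
            k: (str(v) if isinstance(v, Path) else
                [str(p) for p in v] if isinstance(v, tuple) else v)
            for k, v in d.items()
        }

    def validate_paths(self) -> None:
        missing = [
            p
            for p in (self.compounds, self.associations, self.ppi_edges,
                      self.annotation, *self.disease_sources)
            if not Path(p).exists()
        ]
        if self.universe is not None and not self.universe.exists():
            missing.append(self.universe)
        if missing:
            raise PipelineError("config", f"missing input file(s): {[str(m) for m in missing]}")


@dataclass
class RunReport:
    """Counts at every stage plus a parameter echo and output-file hashes."""

    parameters: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    truncated_core_extraction: bool = False
    top_compounds: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)  # relative path -> sha256

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage in order, writing all stage outputs under ``config.outdir``."""
    config.validate_paths()
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(parameters=config.echo())
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        p = out / name
        writer(p)
        written.append(p)
        return p

    # -- screen ------------------------------------------------------------
    try:
        table = io.read_compound_tsv(config.compounds)
        screened = screen_compounds(table, config.ob_min, config.dl_min, config.score_min)
    except ValueError as e:
        raise PipelineError("screen", str(e)) from e
    logger.info("screen: %d/%d compounds pass", len(screened), len(table))
    emit("screened_compounds.tsv", lambda p: io.write_compound_tsv(screened, p))
    report.counts["compounds_in"] = len(table)
    report.counts["compounds_screened"] = len(screened)

    associations = io.read_association_tsv(config.associations)
    targets = collect_targets(screened, associations)
    emit("drug_targets.txt", lambda p: io.write_gene_list(targets, p))
    report.counts["drug_targets"] = len(targets)
    logger.info("targets: %d nonredundant genes", len(targets))

    # -- merge disease sources ----------------------------------------------
    try:
        sources = {p.stem: io.read_gene_list(p) for p in config.disease_sources}
        disease = merge_sources(sources)
    except ValueError as e:
        raise PipelineError("merge-disease", str(e)) from e
    emit("disease_genes.txt", lambda p: io.write_gene_list(disease, p))
    report.counts["disease_sources"] = len(sources)
    report.counts["disease_genes"] = len(disease)
    logger.info("disease: %d genes from %d sources", len(disease), len(sources))

    # -- intersect + effective compounds ------------------------------------
    intersection = intersect_targets(targets, disease)
    emit("intersection.txt", lambda p: io.write_gene_list(intersection, p))
    effective = effective_compounds(intersection, associations, screened)
    emit("effective_compounds.tsv", lambda p: io.write_compound_tsv(effective, p))
    report.counts["intersection_genes"] = len(intersection)
    report.counts["effective_compounds"] = len(effective)
    logger.info(
        "intersection: %d genes, %d effective compounds", len(intersection), len(effective)
    )

    # -- tripartite network --------------------------------------------------
    tripartite = build_tripartite(screened, associations, intersection)
    emit("tripartite.sif", lambda p: export_network(tripartite, "sif", p))
    emit("tripartite_edges.tsv", lambda p: export_network(tripartite, "tsv", p))
    if tripartite.number_of_nodes():
        report.top_compounds = rank_compounds_by_degree(tripartite, k=10)
    report.counts["tripartite_nodes"] = tripartite.number_of_nodes()
    report.counts["tripartite_edges"] = tripartite.number_of_edges()

    # -- core extraction ------------------------------------------------------
    try:
        # the edge file IS the primary network (e.g. a STRING export for the
        # intersection genes); it is taken as supplied, not recomputed
        primary = build_ppi(io.read_edge_tsv(config.ppi_edges), config.min_confidence)
        report.counts["primary_nodes"] = primary.number_of_nodes()
        report.counts["primary_edges"] = primary.number_of_edges()
        if primary.number_of_nodes() == 0:
            raise ValueError("primary PPI network is empty")
        result = extract_core(primary, steps=config.steps)
    except ValueError as e:
        raise PipelineError("core-extract", str(e)) from e
    for i, step in enumerate(result.steps, start=1):
        emit(f"centrality_step{i}.tsv", lambda p, s=step: write_centrality_tsv(s.table, p))
        report.counts[f"core_step{i}_nodes"] = step.graph.number_of_nodes()
        report.counts[f"core_step{i}_edges"] = step.graph.number_of_edges()
    core = result.core
    emit("core.sif", lambda p: export_network(core, "sif", p))
    emit("core.graphml", lambda p: export_network(core, "graphml", p))
    emit("core_nodes.txt", lambda p: io.write_gene_list(sorted(core.nodes), p))
    report.truncated_core_extraction = result.truncated
    report.counts["core_nodes"] = core.number_of_nodes()
    report.counts["core_edges"] = core.number_of_edges()
    logger.info(
        "core: %d nodes, %d edges (truncated=%s)",
        core.number_of_nodes(),
        core.number_of_edges(),
        result.truncated,
    )

    # -- enrichment -----------------------------------------------------------
    try:
        annotation = io.read_annotation_tsv(config.annotation)
        universe = io.read_gene_list(config.universe) if config.universe else None
        query = GeneSet.from_symbols("core", core.nodes)
        rows = enrich(query, annotation, universe)
    except ValueError as e:
        raise PipelineError("enrich", str(e)) from e
    emit(
        "enrichment.tsv",
        lambda p: rows_to_frame(rows).to_csv(
            p, sep="\t", index=False, lineterminator="\n", encoding="utf-8"
        ),
    )
    top = select_top(
        rows,
        q_max=config.q_max,
        per_category={"BP": config.top_go, "CC": config.top_go,
                      "MF": config.top_go, "KEGG": config.top_kegg},
    )
    emit(
        "top_terms.tsv",
        lambda p: rows_to_frame(top).to_csv(
            p, sep="\t", index=False, lineterminator="\n", encoding="utf-8"
        ),
    )
    sig = [r for r in rows if r.q <= config.q_max]
    for cat in ("BP", "CC", "MF", "KEGG"):
        report.counts[f"significant_terms_{cat}"] = sum(1 for r in sig if r.category == cat)
    report.counts["significant_terms"] = len(sig)
    logger.info("enrichment: %d significant terms at q <= %g", len(sig), config.q_max)

    report.outputs = {p.name: _sha256(p) for p in sorted(written)}
    (out / "report.json").write_text(report.to_json(), encoding="utf-8")
    return report


def simulate(
    outdir: PathLike,
    seed: int,
    preset: str = "paper-scale",
    overrides: Optional[dict] = None,
) -> dict[str, Path]:
    """Materialize a synthetic input bundle under ``outdir``; returns file paths.

    The only preset, ``paper-scale``, mirrors the scale of a seven-herb
    analysis (150-node PPI graph with a 23-node planted core); individual
    generator parameters can be overridden.
    """
    if preset != "paper-scale":
        raise ValueError(f"unknown preset {preset!r}")
    bundle = synthetic.gen_bundle(seed, **(overrides or {}))
    paths = synthetic.write_bundle(bundle, outdir)
    logger.info("simulate: wrote %d files to %s", len(paths), outdir)
    return paths


def config_for_bundle(
    bundle_dir: PathLike, outdir: PathLike, seed: int = 0, **kwargs
) -> PipelineConfig:
    """Convenience: a PipelineConfig pointing at files written by :func:`simulate`."""
    bundle_dir = Path(bundle_dir)
    return PipelineConfig(
        compounds=bundle_dir / "compounds.tsv",
        associations=bundle_dir / "associations.tsv",
        disease_sources=tuple(sorted(bundle_dir.glob("disease_source*.txt"))),
        ppi_edges=bundle_dir / "ppi_edges.tsv",
        annotation=bundle_dir / "annotation.tsv",
        outdir=Path(outdir),
        seed=seed,
        **kwargs,
    )
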