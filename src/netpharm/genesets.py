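"""Disease-gene merging, target intersection, and effective-compound lookup.

Multi-source disease gene lists are combined by plain set union (no voting or
frequency weighting), with per-gene provenance retained so reports can show
which sources contributed each gene. The intersection of drug targets with
disease genes defines the candidate therapeutic targets, and the screened
compounds hitting at least one intersection gene are the "effective"
compounds carried into the network stage.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .records import CompoundRecord, GeneSet, TargetAssociation

__all__ = ["merge_sources", "intersect_targets", "effective_compounds"]


def merge_sources(sources: Mapping[str, GeneSet]) -> GeneSet:
    """Union of named gene sets with per-gene provenance.

    Sources are processed in sorted-name order, so the result (including
    provenance ordering) is deterministic. Raises on an empty collection.
    """
    if not sources:
        raise ValueError("at least one source is required")
    gene_sources: dict[str, list[str]] = {}
    for name in sorted(sources):
        for g in sources[name].genes:
            gene_sources.setdefault(g, []).append(name)
    return GeneSet(
        name="merged",
        genes=frozenset(gene_sources),
        provenance=tuple(sorted(sources)),
        gene_sources={g: tuple(v) for g, v in gene_sources.items()},
    )


def intersect_targets(drug_targets: GeneSet, disease_genes: GeneSet) -> GeneSet:
    """Exact set intersection of drug targets and disease genes."""
    common = drug_targets.genes & disease_genes.genes
    return GeneSet(
        name="intersection",
        genes=frozenset(common),
        provenance=(drug_targets.name, disease_genes.name),
    )


def effective_compounds(
    intersection: GeneSet,
    associations: Iterable[TargetAssociation],
    screened: Sequence[CompoundRecord],
) -> list[CompoundRecord]:
    """Screened compounds with at least one association into the intersection set.

    Output preserves the input order of ``screened`` and is always a subset
    of it.
    """
    hit_ids = {
        a.compound_id for a in associations if a.gene in intersection.genes
    }
    return [r for r in screened if r.compound_id in hit_ids]
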