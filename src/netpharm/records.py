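"""Core record types shared across the pipeline.

A herbal formula is modelled as a table of ingredient compounds with
pharmacokinetic screening attributes (oral bioavailability OB, drug-likeness
DL, and an optional database score), a compound->gene association table, and
named gene sets with provenance. Gene symbols are normalized once, at the
boundary, and treated as opaque uppercase tokens everywhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

__all__ = [
    "CompoundRecord",
    "TargetAssociation",
    "GeneSet",
    "AnnotationTerm",
    "AnnotationMap",
    "normalize_symbol",
]


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol: trim, collapse internal whitespace, uppercase.

    No alias resolution is attempted; callers wanting alias remapping apply
    their own table before set operations.
    """
    return " ".join(str(symbol).split()).upper()


@dataclass(frozen=True)
class CompoundRecord:
    """One herb ingredient with its pharmacokinetic screening attributes.

    Parameters
    ----------
    compound_id
        Opaque identifier, unique within a table.
    herb
        Name of the herb the ingredient was catalogued under.
    name
        Compound name (used for deterministic tie-breaking in rankings).
    OB
        Oral bioavailability, percent, in [0, 100].
    DL
        Drug-likeness, unitless, in [0, 1].
    score
        Database relevance score, unitless nonnegative; ``None`` when the
        source database supplies no score.
    """

    compound_id: str
    herb: str
    name: str
    OB: float
    DL: float
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.OB <= 100.0:
            raise ValueError(f"OB must lie in [0, 100], got {self.OB!r}")
        if not 0.0 <= self.DL <= 1.0:
            raise ValueError(f"DL must lie in [0, 1], got {self.DL!r}")
        if self.score is not None:
            if math.isnan(self.score):
                object.__setattr__(self, "score", None)
            elif self.score < 0:
                raise ValueError(f"score must be nonnegative, got {self.score!r}")


@dataclass(frozen=True)
class TargetAssociation:
    """A (compound, gene) association; the gene symbol is normalized on construction."""

    compound_id: str
    gene: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_symbol(self.gene))


@dataclass(frozen=True)
class GeneSet:
    """A named, normalized set of gene symbols with provenance.

    ``provenance`` lists contributing source labels; ``gene_sources``
    optionally records, per gene, which sources contributed it (populated by
    :func:`netpharm.genesets.merge_sources`).
    """

    name: str
    genes: frozenset[str]
    provenance: tuple[str, ...] = ()
    gene_sources: Optional[Mapping[str, tuple[str, ...]]] = None

    @classmethod
    def from_symbols(
        cls,
        name: str,
        symbols: Iterable[str],
        provenance: Iterable[str] = (),
    ) -> "GeneSet":
        return cls(
            name=name,
            genes=frozenset(normalize_symbol(s) for s in symbols),
            provenance=tuple(provenance),
        )

    def sorted(self) -> list[str]:
        """Deterministically sorted symbol list (lexicographic)."""
        return sorted(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: object) -> bool:
        return symbol in self.genes

    def __iter__(self):
        return iter(self.sorted())


@dataclass(frozen=True)
class AnnotationTerm:
    """One annotation term (GO BP/CC/MF or KEGG pathway) and its gene membership."""

    term_id: str
    term_name: str
    category: str  # one of {"BP", "CC", "MF", "KEGG"}
    genes: frozenset[str]

    CATEGORIES = ("BP", "CC", "MF", "KEGG")

    def __post_init__(self) -> None:
        if self.category not in self.CATEGORIES:
            raise ValueError(
                f"category must be one of {self.CATEGORIES}, got {self.category!r}"
            )


@dataclass
class AnnotationMap:
    """term_id -> AnnotationTerm mapping with a derived gene universe."""

    terms: dict[str, AnnotationTerm] = field(default_factory=dict)

    def add(self, term: AnnotationTerm) -> None:
        self.terms[term.term_id] = term

    def universe(self) -> frozenset[str]:
        """All genes annotated to at least one term."""
        out: set[str] = set()
        for t in self.terms.values():
            out |= t.genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(sorted(self.terms))

    def __getitem__(self, term_id: str) -> AnnotationTerm:
        return self.terms[term_id]
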