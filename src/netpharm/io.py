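"""Tabular readers and writers for the pipeline's plain-text formats.

Every TSV carries a single header row, is UTF-8 encoded and uses LF line
endings; gene-list files hold one symbol per line. All writers sort rows
deterministically so that identical in-memory objects produce byte-identical
files.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .records import (
    AnnotationMap,
    AnnotationTerm,
    CompoundRecord,
    GeneSet,
    TargetAssociation,
    normalize_symbol,
)

PathLike = Union[str, Path]

_COMPOUND_COLS = ["compound_id", "herb", "name", "OB", "DL", "score"]


def write_compound_tsv(records: Sequence[CompoundRecord], path: PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "herb": r.herb,
                "name": r.name,
                "OB": r.OB,
                "DL": r.DL,
                "score": "" if r.score is None else repr(r.score),
            }
            for r in records
        ],
        columns=_COMPOUND_COLS,
    )
    _write_tsv(df, path)


def read_compound_tsv(path: PathLike) -> list[CompoundRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str, "herb": str, "name": str})
    records = []
    for row in df.itertuples(index=False):
        score = getattr(row, "score", None)
        if score is None or (isinstance(score, float) and math.isnan(score)):
            score = None
        else:
            score = float(score)
        records.append(
            CompoundRecord(
                compound_id=row.compound_id,
                herb=row.herb,
                name=row.name,
                OB=float(row.OB),
                DL=float(row.DL),
                score=score,
            )
        )
    ids = [r.compound_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate compound_id in {path}")
    return records


def write_association_tsv(pairs: Iterable[TargetAssociation], path: PathLike) -> None:
    rows = sorted({(p.compound_id, p.gene) for p in pairs})
    df = pd.DataFrame(rows, columns=["compound_id", "gene"])
    _write_tsv(df, path)


def read_association_tsv(path: PathLike) -> list[TargetAssociation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [TargetAssociation(row.compound_id, row.gene) for row in df.itertuples(index=False)]


def write_gene_list(genes: Union[GeneSet, Iterable[str]], path: PathLike) -> None:
    symbols = genes.sorted() if isinstance(genes, GeneSet) else sorted(
        {normalize_symbol(g) for g in genes}
    )
    Path(path).write_text("".join(s + "\n" for s in symbols), encoding="utf-8")


def read_gene_list(path: PathLike, name: str | None = None) -> GeneSet:
    path = Path(path)
    symbols = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    return GeneSet.from_symbols(name or path.stem, symbols, provenance=(name or path.stem,))


def write_edge_tsv(
    edges: Iterable[tuple[str, str, float]] | Iterable[tuple[str, str]],
    path: PathLike,
) -> None:
    """Write a PPI edge table (gene_a, gene_b, confidence).

    Each undirected edge is stored once, with its endpoints in lexicographic
    order; a missing confidence defaults to 1.0.
    """
    rows = []
    for e in edges:
        a, b = normalize_symbol(e[0]), normalize_symbol(e[1])
        conf = float(e[2]) if len(e) > 2 else 1.0
        if a > b:
            a, b = b, a
        rows.append((a, b, conf))
    df = pd.DataFrame(sorted(set(rows)), columns=["gene_a", "gene_b", "confidence"])
    _write_tsv(df, path)


def read_edge_tsv(path: PathLike) -> list[tuple[str, str, float]]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    out = []
    for row in df.itertuples(index=False):
        conf = float(getattr(row, "confidence", 1.0))
        out.append((normalize_symbol(row.gene_a), normalize_symbol(row.gene_b), conf))
    return out


def write_annotation_tsv(annotation: AnnotationMap, path: PathLike) -> None:
    rows = []
    for term_id in sorted(annotation.terms):
        t = annotation.terms[term_id]
        for g in sorted(t.genes):
            rows.append((t.term_id, t.term_name, t.category, g))
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "category", "gene"])
    _write_tsv(df, path)


def read_annotation_tsv(path: PathLike) -> AnnotationMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    amap = AnnotationMap()
    for (term_id, term_name, category), grp in df.groupby(
        ["term_id", "term_name", "category"], sort=True
    ):
        amap.add(
            AnnotationTerm(
                term_id=term_id,
                term_name=term_name,
                category=category,
                genes=frozenset(normalize_symbol(g) for g in grp["gene"]),
            )
        )
    return amap


def _write_tsv(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")
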