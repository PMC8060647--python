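"""Over-representation analysis with exact hypergeometric tails and BH FDR.

For a query gene set of size n drawn against a universe of N annotated
genes, a term annotating K genes and hit k times has tail probability
P(X >= k), X ~ Hypergeometric(N, K, n). One-sided over-representation only.
Benjamini–Hochberg adjustment runs within each category (BP/CC/MF/KEGG)
by default, mirroring per-ontology enrichment tooling; a flag switches to a
single global adjustment. Terms are tested only when hit at least once, so
the BH family size per category is the number of tested terms in it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .records import AnnotationMap, GeneSet

__all__ = ["hypergeom_tail", "bh_adjust", "enrich", "select_top", "EnrichmentRow"]

logger = logging.getLogger(__name__)


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` genes in the universe, ``K`` annotated to the term, ``n`` in the
    query, ``k`` hits. Evaluated through the survival function (log-space
    internally), exact at over-representation scales.
    """
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
    if n > N or K > N:
        raise ValueError(f"margins exceed universe: n={n}, K={K}, N={N}")
    if k > min(n, K):
        raise ValueError(f"k={k} exceeds min(n, K)={min(n, K)}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, returned in input order.

    q(i) = min over j >= i of m * p(j) / j on the ascending p-values,
    capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


@dataclass(frozen=True)
class EnrichmentRow:
    """One term's 2x2 over-representation result."""

    term_id: str
    term_name: str
    category: str
    k: int  # query hits
    K: int  # term size within universe
    n: int  # query size within universe
    N: int  # universe size
    p: float
    q: float


def enrich(
    query: GeneSet,
    annotation: AnnotationMap,
    universe: GeneSet | None = None,
    per_category_fdr: bool = True,
) -> list[EnrichmentRow]:
    """Test every term hit by the query; returns rows sorted by (q, p, term_id).

    The universe defaults to all annotated genes. Query genes outside the
    universe are dropped with a logged warning; term gene sets are clipped to
    the universe before counting.
    """
    uni = universe.genes if universe is not None else annotation.universe()
    if not uni:
        raise ValueError("universe must be nonempty")
    q_genes = query.genes & uni
    dropped = len(query.genes) - len(q_genes)
    if dropped:
        logger.warning("enrich: dropped %d query gene(s) outside the universe", dropped)
    n, big_n = len(q_genes), len(uni)

    tested: list[tuple[str, str, str, int, int, float]] = []
    for term_id in sorted(annotation.terms):
        t = annotation.terms[term_id]
        term_genes = t.genes & uni
        k = len(q_genes & term_genes)
        if k < 1:
            continue
        p = hypergeom_tail(k, n, len(term_genes), big_n)
        tested.append((term_id, t.term_name, t.category, k, len(term_genes), p))

    rows: list[EnrichmentRow] = []
    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(tested):
        groups.setdefault(rec[2] if per_category_fdr else "_all_", []).append(i)
    qvals = [float("nan")] * len(tested)
    for idx in groups.values():
        adj = bh_adjust([tested[i][5] for i in idx])
        for i, qv in zip(idx, adj):
            qvals[i] = qv
    for (term_id, term_name, category, k, big_k, p), qv in zip(tested, qvals):
        rows.append(
            EnrichmentRow(
                term_id=term_id,
                term_name=term_name,
                category=category,
                k=k,
                K=big_k,
                n=n,
                N=big_n,
                p=p,
                q=qv,
            )
        )
    rows.sort(key=lambda r: (r.q, r.p, r.term_id))
    return rows


def select_top(
    rows: Sequence[EnrichmentRow],
    q_max: float = 0.05,
    per_category: Union[int, Mapping[str, int]] = 10,
) -> list[EnrichmentRow]:
    """Significant rows (q <= q_max), truncated per category.

    ``per_category`` is either one limit for every category or a mapping
    like ``{"BP": 10, "CC": 10, "MF": 10, "KEGG": 30}``. Within a category
    rows are ordered by ascending q, then p, then term_id (the documented
    tie rule), and the first limit rows are kept.
    """
    if isinstance(per_category, int):
        if per_category <= 0:
            raise ValueError("per_category must be positive")
        limits: Mapping[str, int] = {}
        default = per_category
    else:
        limits = per_category
        default = 0
        if any(v <= 0 for v in limits.values()):
            raise ValueError("per-category limits must be positive")
    sig = sorted(
        (r for r in rows if r.q <= q_max), key=lambda r: (r.q, r.p, r.term_id)
    )
    kept: list[EnrichmentRow] = []
    counts: dict[str, int] = {}
    for r in sig:
        limit = limits.get(r.category, default) if limits else default
        if counts.get(r.category, 0) < limit:
            kept.append(r)
            counts[r.category] = counts.get(r.category, 0) + 1
    return kept


def rows_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    """Enrichment rows as a DataFrame (column order matches the TSV schema)."""
    return pd.DataFrame(
        [
            (r.term_id, r.term_name, r.category, r.k, r.K, r.n, r.N, r.p, r.q)
            for r in rows
        ],
        columns=["term_id", "term_name", "category", "k", "K", "n", "N", "p", "q"],
    )
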