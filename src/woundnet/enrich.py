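"""Hypergeometric over-representation analysis of KEGG pathways and GO terms.

Given a query gene set (network nodes, a cluster, a bridge list) and an
annotation catalog, each term is scored with the exact hypergeometric upper
tail P(X >= k) where k is the query/term overlap. Benjamini-Hochberg false
discovery control is applied separately within each category (KEGG and GO are
reported separately), and significant terms can then be intersected with a
user-supplied reference list of process-relevant term ids.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import FormatError, UsageError

__all__ = [
    "CatalogTerm",
    "AnnotationCatalog",
    "EnrichmentRow",
    "hypergeometric_tail",
    "enrich",
    "match_reference",
    "read_gmt",
    "read_term_list",
    "write_enrichment",
]

CATEGORIES = ("KEGG", "GO")


@dataclass(frozen=True)
class CatalogTerm:
    term_id: str
    category: str  # "KEGG" or "GO"
    name: str
    genes: frozenset[str]


@dataclass(frozen=True)
class AnnotationCatalog:
    """Term-to-gene-set catalog with an explicit background universe."""

    terms: tuple[CatalogTerm, ...]
    background: frozenset[str]

    def __post_init__(self) -> None:
        seen = set()
        for term in self.terms:
            if term.term_id in seen:
                raise UsageError(f"duplicate term id {term.term_id!r} in catalog")
            seen.add(term.term_id)
            if not term.genes <= self.background:
                raise UsageError(
                    f"term {term.term_id!r} annotates genes outside the background"
                )

    def terms_annotating(self, gene: str, category: str | None = None) -> list[CatalogTerm]:
        return [
            t
            for t in self.terms
            if gene in t.genes and (category is None or t.category == category)
        ]


@dataclass(frozen=True)
class EnrichmentRow:
    """One tested term: overlap k out of term size K, query n, background N."""

    term_id: str
    category: str
    name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float = 1.0
    significant: bool = False


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= k), X ~ Hypergeometric(N, K, n).

    N is the background size, K the term size, n the query size and k the
    observed overlap. Exact (no normal approximation).
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if K > N or n > N:
        raise ValueError(f"require K <= N and n <= N; got K={K}, n={n}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: Iterable[str],
    catalog: AnnotationCatalog,
    alpha: float = 0.001,
    threshold_on: str = "q",
) -> list[EnrichmentRow]:
    """Test every catalog term for over-representation in ``query``.

    Only terms overlapping the query (k >= 1) are tested. BH adjustment is
    computed over all tested terms within each category. ``threshold_on``
    selects whether ``significant`` compares ``alpha`` against the adjusted
    value (``"q"``, default) or the raw p-value (``"p"``). Rows are sorted by
    ascending p, ties by term id.
    """
    if not 0 < alpha < 1:
        raise UsageError(f"alpha must be in (0, 1), got {alpha}")
    if threshold_on not in ("p", "q"):
        raise UsageError("threshold_on must be 'p' or 'q'")
    query_set = frozenset(query) & catalog.background
    if not query_set:
        raise UsageError("query has no genes in the catalog background")
    N = len(catalog.background)
    n = len(query_set)
    rows = []
    for term in catalog.terms:
        k = len(term.genes & query_set)
        if k == 0:
            continue
        p = hypergeometric_tail(k, len(term.genes), n, N)
        rows.append(
            EnrichmentRow(term.term_id, term.category, term.name, k, len(term.genes), n, N, p)
        )
    out: list[EnrichmentRow] = []
    for category in sorted({r.category for r in rows}):
        group = [r for r in rows if r.category == category]
        qvals = multipletests([r.p for r in group], method="fdr_bh")[1]
        for row, q in zip(group, qvals):
            value = q if threshold_on == "q" else row.p
            out.append(replace(row, q=float(q), significant=bool(value < alpha)))
    out.sort(key=lambda r: (r.p, r.term_id))
    return out


def match_reference(
    rows: Sequence[EnrichmentRow], reference_ids: Iterable[str]
) -> tuple[list[EnrichmentRow], int]:
    """Significant rows whose term id appears in the reference list."""
    reference = frozenset(reference_ids)
    matched = [r for r in rows if r.significant and r.term_id in reference]
    return matched, len(matched)


def _infer_category(term_id: str) -> str:
    return "GO" if term_id.upper().startswith("GO") else "KEGG"


def read_gmt(
    path: str | os.PathLike[str],
    background: Iterable[str] | None = None,
) -> AnnotationCatalog:
    """Read a GMT catalog (term_id TAB name TAB gene TAB gene ...).

    Categories are inferred from the term id ("GO:"-prefixed ids are GO,
    everything else KEGG). The background defaults to the union of all
    annotated genes; pass one explicitly to use e.g. all network nodes.
    """
    terms = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"GMT line {lineno} has {len(parts)} fields; need term, name, >=1 gene"
                )
            term_id, name, *genes = parts
            genes = [g.strip() for g in genes if g.strip()]
            terms.append(
                CatalogTerm(term_id.strip(), _infer_category(term_id), name.strip(),
                            frozenset(genes))
            )
    if background is None:
        universe: frozenset[str] = frozenset().union(*(t.genes for t in terms)) if terms else frozenset()
    else:
        universe = frozenset(background) | frozenset().union(
            *(t.genes for t in terms)
        ) if terms else frozenset(background)
    return AnnotationCatalog(terms=tuple(terms), background=universe)


def read_term_list(path: str | os.PathLike[str]) -> frozenset[str]:
    """One term id per line; ``#`` starts a comment."""
    ids = set()
    with open(path) as handle:
        for line in handle:
            term = line.split("#", 1)[0].strip()
            if term:
                ids.add(term)
    return frozenset(ids)


def write_enrichment(rows: Sequence[EnrichmentRow], path: str | os.PathLike[str]) -> None:
    frame = pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "category": r.category,
                "name": r.name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p": r.p,
                "q": r.q,
                "significant": r.significant,
            }
            for r in rows
        ]
    )
    frame.to_csv(path, sep="\t", index=False)
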