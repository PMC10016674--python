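"""Term over-representation analysis and between-analysis term comparison.

Candidate gene lists are tested against term gene-sets (GO molecular
function, Reactome, CORUM, KEGG — read from GMT) with the one-sided
hypergeometric (Fisher) upper-tail test, against an annotated-gene universe
(all genes in the term database unless overridden). Raw p-values are
adjusted by Benjamini–Hochberg (default) or Bonferroni. The hierarchical,
structure-aware g:SCS correction used by g:Profiler has no published
closed form, so BH stands in; output headers state the method.

Two enrichment runs (e.g. the family-overlap genes versus the burden genes)
can be compared: terms significant in both, plus a one-sided two-sample
proportion z-test with continuity correction for whether a term's gene count
grew between analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from scipy.stats import hypergeom, norm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "TermGeneSet",
    "TermEnrichmentRow",
    "read_gmt",
    "write_gmt",
    "hypergeometric_enrichment",
    "adjust_pvalues",
    "common_terms",
    "proportion_increase_test",
]

_SOURCE_PREFIXES = (
    ("GO", "GO_MF"),
    ("REAC", "REAC"),
    ("CORUM", "CORUM"),
    ("KEGG", "KEGG"),
    ("HSA", "KEGG"),
)


def _infer_source(term_id: str) -> str:
    up = term_id.upper()
    for prefix, tag in _SOURCE_PREFIXES:
        if up.startswith(prefix):
            return tag
    return "OTHER"


@dataclass(frozen=True)
class TermGeneSet:
    """One term (pathway/ontology/complex) and its member genes."""

    term_id: str
    term_name: str
    genes: frozenset[str]
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.term_id!r} has an empty gene set")
        if not self.source_tag:
            object.__setattr__(self, "source_tag", _infer_source(self.term_id))


@dataclass
class TermEnrichmentRow:
    term: TermGeneSet
    query_overlap: frozenset[str]
    p_raw: float
    p_adj: float = 1.0

    @property
    def k(self) -> int:
        return len(self.query_overlap)


def read_gmt(path: str | Path) -> list[TermGeneSet]:
    """Read GMT: one term per line, ``id<TAB>name<TAB>gene1<TAB>gene2...``."""
    terms: list[TermGeneSet] = []
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        term_id, name, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if term_id in seen:
            raise ValueError(f"duplicate term id {term_id!r} in GMT")
        seen.add(term_id)
        terms.append(TermGeneSet(term_id, name, frozenset(genes)))
    return terms


def write_gmt(terms: Iterable[TermGeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([t.term_id, t.term_name, *sorted(t.genes)]) for t in terms
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeometric_enrichment(
    query: Iterable[str],
    terms: Sequence[TermGeneSet],
    universe: Optional[Iterable[str]] = None,
) -> list[TermEnrichmentRow]:
    """Hypergeometric over-representation of ``query`` in each term.

    The universe defaults to all genes annotated to any term (the annotated-
    gene convention). Query genes outside the universe are dropped with a
    log message; term gene-sets are intersected with the universe first.
    ``p_raw = P(X >= k)`` for ``X ~ Hypergeom(N=|universe|, K=|term|,
    n=|query|)``. Rows are sorted by raw p (ties by term id).
    """
    if universe is None:
        universe_set = set().union(*(t.genes for t in terms)) if terms else set()
    else:
        universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty gene universe")
    query_set = set(query)
    dropped = query_set - universe_set
    if dropped:
        logger.info("dropping %d query genes outside universe: %s",
                    len(dropped), sorted(dropped)[:5])
    query_set &= universe_set
    N, n = len(universe_set), len(query_set)
    rows: list[TermEnrichmentRow] = []
    for t in terms:
        term_genes = t.genes & universe_set
        if not term_genes:
            continue
        overlap = frozenset(query_set & term_genes)
        k, K = len(overlap), len(term_genes)
        # upper tail P(X >= k) == sf(k - 1)
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append(TermEnrichmentRow(term=t, query_overlap=overlap,
                                      p_raw=min(1.0, p)))
    rows.sort(key=lambda r: (r.p_raw, r.term.term_id))
    return rows


def adjust_pvalues(
    rows: Sequence[TermEnrichmentRow], method: str = "bh"
) -> list[TermEnrichmentRow]:
    """Fill ``p_adj`` in place by Benjamini–Hochberg or Bonferroni."""
    if method not in ("bh", "bonferroni"):
        raise ValueError(f"unknown adjustment method {method!r}")
    if not rows:
        return list(rows)
    sm_method = "fdr_bh" if method == "bh" else "bonferroni"
    _, adj, _, _ = multipletests([r.p_raw for r in rows], method=sm_method)
    for r, p in zip(rows, adj):
        r.p_adj = float(p)
    return list(rows)


def common_terms(
    rows_a: Sequence[TermEnrichmentRow],
    rows_b: Sequence[TermEnrichmentRow],
    alpha: float = 0.01,
) -> list[tuple[TermGeneSet, int, int]]:
    """Terms significant (raw p < alpha) in both analyses.

    Returns (term, gene count in analysis A, gene count in analysis B)
    tuples sorted by term id; counts are distinct query genes in the term.
    """
    sig_a = {r.term.term_id: r for r in rows_a if r.p_raw < alpha}
    sig_b = {r.term.term_id: r for r in rows_b if r.p_raw < alpha}
    out = [
        (sig_a[tid].term, sig_a[tid].k, sig_b[tid].k)
        for tid in sorted(set(sig_a) & set(sig_b))
    ]
    return out


def proportion_increase_test(k_a: int, n_a: int, k_b: int, n_b: int) -> float:
    """One-sided two-sample proportion z-test with continuity correction.

    Tests H1: proportion B exceeds proportion A. Pooled estimate
    ``p = (k_a + k_b) / (n_a + n_b)``; Yates correction
    ``cc = 0.5 * (1/n_a + 1/n_b)``;
    ``z = (p_b - p_a - cc) / sqrt(p (1 - p) (1/n_a + 1/n_b))``; p-value is
    the standard-normal upper tail. Degenerate pooled proportions (0 or 1)
    return 1.0.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k_a <= n_a and 0 <= k_b <= n_b):
        raise ValueError("counts must satisfy 0 <= k <= n")
    pooled = (k_a + k_b) / (n_a + n_b)
    if pooled in (0.0, 1.0):
        return 1.0
    cc = 0.5 * (1 / n_a + 1 / n_b)
    se = (pooled * (1 - pooled) * (1 / n_a + 1 / n_b)) ** 0.5
    z = (k_b / n_b - k_a / n_a - cc) / se
    return float(norm.sf(z))
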