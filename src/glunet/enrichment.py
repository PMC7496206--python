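"""Over-representation analysis and functional keyword sub-networks.

Enrichment of a query gene set against term sets is tested with the
upper-tail hypergeometric probability P(X >= k) for k query hits in a
term of size K, query size n, background size N, with
Benjamini-Hochberg (default) or Bonferroni multiple-testing adjustment.
Raw p-values are always reported alongside adjusted ones.

Keyword sub-networks restrict a regulatory network to genes tagged with
one of the beta-cell functional categories G (glucose/carbon/insulin),
O (ion/calcium), E (exocytosis/homeostasis), C (CREB/cAMP/transcription
factor); a gene may belong to several categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from glunet.network import KeywordAnnotation, NetworkEdge

CATEGORIES = ("G", "O", "E", "C")


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # query hits in term
    K: int  # term size in background
    n: int  # query size
    N: int  # background size
    p_value: float
    adjusted_p: float


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k)."""
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k}, K={K}, n={n}, N={N}")
    # sf(k-1) = P(X >= k); exact for k = 0 too (returns 1)
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def enrich(
    query: set[str],
    term_sets: Mapping[str, set[str]],
    background: set[str],
    correction: str = "bh",
    top: Optional[int] = 20,
) -> list[EnrichmentResult]:
    """Rank term over-representation in ``query`` against ``background``.

    Terms are intersected with the background; only terms with at least
    one query hit are reported, ranked by raw p ascending (ties by term
    id), truncated to ``top`` (None = all).
    """
    if not background:
        raise ValueError("empty background universe")
    if not query <= background:
        raise ValueError("query gene set must be a subset of the background")
    if correction not in ("bh", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}; use 'bh' or 'bonferroni'")
    N, n = len(background), len(query)
    rows: list[tuple[str, int, int, float]] = []
    for term, genes in term_sets.items():
        members = genes & background
        k = len(members & query)
        if k < 1:
            continue
        rows.append((term, k, len(members), hypergeom_test(k, len(members), n, N)))
    if not rows:
        return []
    rows.sort(key=lambda r: (r[3], r[0]))
    pvals = [r[3] for r in rows]
    method = "fdr_bh" if correction == "bh" else "bonferroni"
    adjusted = multipletests(pvals, method=method)[1]
    results = [
        EnrichmentResult(term, k, K, n, N, p, float(min(1.0, adj)))
        for (term, k, K, p), adj in zip(rows, adjusted)
    ]
    return results[:top] if top is not None else results


def keyword_networks(
    edges: Sequence[NetworkEdge],
    annotations: Iterable[KeywordAnnotation],
) -> dict[str, list[NetworkEdge]]:
    """Per-category {G, O, E, C} sub-networks of mti edges.

    An edge is retained in category c iff its target gene carries c;
    genes with several categories appear in each.
    """
    by_gene: dict[str, frozenset[str]] = {a.gene: a.categories for a in annotations}
    out: dict[str, list[NetworkEdge]] = {c: [] for c in CATEGORIES}
    for e in edges:
        if e.edge_kind != "mti":
            continue
        for c in by_gene.get(e.target, frozenset()):
            out[c].append(e)
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT term sets: term <TAB> description <TAB> gene1 <TAB> ..."""
    term_sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: GMT line needs term, description, >=1 gene: {line!r}")
        term_sets[fields[0]] = {g for g in fields[2:] if g}
    return term_sets


def write_gmt(term_sets: Mapping[str, set[str]], path: str | Path) -> Path:
    path = Path(path)
    lines = [
        "\t".join([term, term] + sorted(genes)) for term, genes in sorted(term_sets.items())
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path
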