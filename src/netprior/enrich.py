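"""Over-representation analysis of a gene list against a pathway collection.

Each pathway is tested with the right-tailed hypergeometric probability
P[X >= k] for X ~ Hypergeometric(N, K, n), where N is the universe size, K
the pathway size within the universe, n the query size within the universe
and k their overlap -- the classic one-sided Fisher exact test on a 2x2
table.  Multiplicity is controlled with Benjamini-Hochberg step-up FDR over
ALL tested pathways, including those with zero overlap (they enter the BH
denominator but are omitted from the default report).

The universe defaults to the union of all pathway members when none is
supplied; query genes outside the universe are dropped with a warning, so
p-values are invariant to them.  A pathway connectivity graph links pathway
pairs through the genes their enrichment results share.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .core import GeneSet, GeneSetCollection, GeneSymbol

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "hypergeom_right_tail",
    "bh_adjust",
    "enrich_gene_list",
    "pathway_connectivity",
    "write_enrichment_table",
    "write_pathway_graph",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One tested pathway: overlap, 2x2 counts, raw p and BH-adjusted FDR."""

    pathway: str
    overlap_genes: frozenset
    k: int
    n: int
    K: int
    N: int
    p: float
    fdr: float


def hypergeom_right_tail(k: int, n: int, K: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n).

    N items, K of them marked, n drawn without replacement, X the number of
    marked draws.  Exact survival-function evaluation (log-space stable via
    scipy); k = 0 gives exactly 1.
    """
    if N < 0 or not 0 <= K <= N or not 0 <= n <= N:
        raise ValueError(f"inconsistent counts: k={k}, n={n}, K={K}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"k must satisfy 0 <= k <= min(n, K); got k={k}, n={n}, K={K}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted values, clipped at 1.

    Order is preserved relative to input positions.  Inputs must lie in
    (0, 1].
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out.tolist()


def enrich_gene_list(
    query: GeneSet,
    pathways: GeneSetCollection,
    universe: Optional[Iterable[GeneSymbol]] = None,
    report_empty: bool = False,
) -> List[EnrichmentResult]:
    """Test the query against every pathway; return results sorted by FDR.

    All counts are restricted to the universe.  Every pathway is tested (a
    zero-overlap pathway scores p = 1) and counts toward the BH denominator;
    by default only pathways with k >= 1 are reported.  Output is sorted by
    (fdr, p, pathway name).
    """
    if universe is None:
        universe_set = set(pathways.union_members())
    else:
        universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe must be non-empty")

    query_in = query.members & universe_set
    dropped = query.members - universe_set
    if dropped:
        logger.warning(
            "dropping %d query gene(s) outside the universe: %s",
            len(dropped),
            ",".join(sorted(dropped)[:8]),
        )
    if not query_in:
        raise ValueError("query has no genes inside the universe")

    N = len(universe_set)
    n = len(query_in)
    rows = []
    for pw in pathways:
        members_in = pw.members & universe_set
        overlap = frozenset(members_in & query_in)
        K = len(members_in)
        k = len(overlap)
        p = hypergeom_right_tail(k, n, K, N) if K else 1.0
        rows.append((pw.name, overlap, k, K, p))

    fdrs = bh_adjust([r[4] for r in rows])
    results = [
        EnrichmentResult(
            pathway=name, overlap_genes=overlap, k=k, n=n, K=K, N=N, p=p, fdr=fdr
        )
        for (name, overlap, k, K, p), fdr in zip(rows, fdrs)
        if k >= 1 or report_empty
    ]
    results.sort(key=lambda r: (r.fdr, r.p, r.pathway))
    return results


def pathway_connectivity(results: Sequence[EnrichmentResult]) -> nx.Graph:
    """Graph on enriched pathways; edges join pairs sharing overlap genes.

    Node attributes: ``fdr``; edge attributes: ``weight`` (shared-gene count)
    and ``shared`` (sorted gene list).  Only pairs with >= 1 shared gene get
    an edge.
    """
    graph = nx.Graph()
    for res in results:
        graph.add_node(res.pathway, fdr=res.fdr)
    for i, a in enumerate(results):
        for b in results[i + 1 :]:
            shared = a.overlap_genes & b.overlap_genes
            if shared:
                graph.add_edge(a.pathway, b.pathway, weight=len(shared), shared=sorted(shared))
    return graph


def write_enrichment_table(results: Sequence[EnrichmentResult], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("pathway\tk\tK\tn\tN\tp\tfdr\tenriched_genes\n")
        for r in results:
            fh.write(
                f"{r.pathway}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{r.p:.6g}\t{r.fdr:.6g}\t{','.join(sorted(r.overlap_genes))}\n"
            )


def write_pathway_graph(graph: nx.Graph, sif_path, edges_path) -> None:
    """Export the connectivity graph as SIF and as a weighted edge-list TSV."""
    edges = sorted(graph.edges(data=True))
    with open(sif_path, "w", encoding="utf-8", newline="") as fh:
        for a, b, _ in edges:
            fh.write(f"{a}\tshares_genes\t{b}\n")
    with open(edges_path, "w", encoding="utf-8", newline="") as fh:
        fh.write("pathway_a\tpathway_b\tshared_count\tshared_genes\n")
        for a, b, data in edges:
            fh.write(f"{a}\t{b}\t{data['weight']}\t{','.join(data['shared'])}\n")
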