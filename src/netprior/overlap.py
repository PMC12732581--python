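"""Multi-set intersection analysis.

Decomposes up to six gene sets into their Venn regions (each gene lands in
exactly one region, identified by its membership signature), counts, for each
gene of a focus list, how many annotation sets contain it, and extracts the
core overlap -- focus genes implicated in at least one annotation category.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, List, Sequence

from .core import GeneSet, GeneSymbol

__all__ = ["VennRegion", "venn_regions", "membership_counts", "core_overlap", "write_region_table"]


@dataclass(frozen=True)
class VennRegion:
    """One region of a Venn decomposition.

    ``signature`` has one boolean per input set; a gene belongs to this region
    iff its memberships match the signature exactly.  The all-false signature
    never occurs (such genes are outside the union).
    """

    signature: tuple
    genes: frozenset

    def __post_init__(self) -> None:
        if not any(self.signature):
            raise ValueError("region signature must include at least one set")


def venn_regions(sets: Sequence[GeneSet], include_empty: bool = False) -> List[VennRegion]:
    """Partition the union of ``sets`` into Venn regions.

    Returns the non-empty regions among the 2^k - 1 candidate signatures
    (or all of them when ``include_empty``), ordered by signature with the
    first set's bit most significant.  2 <= k <= 6 input sets are supported;
    five-set diagrams have 31 candidate regions, most empty in practice,
    hence the sparse default.
    """
    k = len(sets)
    if k < 2:
        raise ValueError(f"need at least 2 sets for a Venn decomposition, got {k}")
    if k > 6:
        raise ValueError(f"at most 6 sets supported, got {k}")
    union: set = set()
    for s in sets:
        union |= s.members
    by_signature: Dict[tuple, set] = {}
    for gene in union:
        signature = tuple(gene in s.members for s in sets)
        by_signature.setdefault(signature, set()).add(gene)
    regions = []
    for bits in product((True, False), repeat=k):
        if not any(bits):
            continue
        genes = by_signature.get(bits, set())
        if genes or include_empty:
            regions.append(VennRegion(signature=bits, genes=frozenset(genes)))
    return regions


def membership_counts(focus: GeneSet, annotation_sets: Sequence[GeneSet]) -> Dict[GeneSymbol, int]:
    """Count, per focus gene, the annotation sets containing it (uncapped).

    Counts run 0..len(annotation_sets); any scoring cap is policy applied
    downstream.  Invariant under permutation of ``annotation_sets``.
    """
    if not annotation_sets:
        raise ValueError("annotation_sets must be non-empty")
    return {
        gene: sum(gene in s.members for s in annotation_sets)
        for gene in sorted(focus.members)
    }


def core_overlap(focus: GeneSet, annotation_sets: Sequence[GeneSet]) -> frozenset:
    """Focus genes with membership count >= 1 (the core overlap list).

    Equals ``focus ∩ (union of annotation sets)``; may be empty when the
    focus is disjoint from every annotation set.
    """
    counts = membership_counts(focus, annotation_sets)
    return frozenset(g for g, c in counts.items() if c >= 1)


def write_region_table(regions: Sequence[VennRegion], path) -> None:
    """Write regions as TSV: signature bitstring, size, comma-joined genes."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("signature\tsize\tgenes\n")
        for region in regions:
            bits = "".join("1" if b else "0" for b in region.signature)
            fh.write(f"{bits}\t{len(region.genes)}\t{','.join(sorted(region.genes))}\n")
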