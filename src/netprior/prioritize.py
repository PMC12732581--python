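"""The 0-5 gene prioritization rubric, ranking, and panel selection.

Each downstream gene of the inhibited target earns one point for a direct
(shortest-path) interaction, one point for annotated transcriptional
regulation, and 1-3 points for co-occurrence in 1, 2 or >= 3 cancer-related
annotation sets.  The cap at 3 overlap points follows the stated rubric even
when four annotation sets are available; it is exposed as a parameter.
Panel selection (score threshold plus explicit manual curation and the
inhibited target itself as anchor) is configuration, never hard-coded,
because published panels mix rubric output with editorial judgement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .core import GeneSet, GeneSymbol, InteractionRecord, Mechanism, normalize_symbol
from .overlap import membership_counts

__all__ = [
    "PriorityRecord",
    "PanelSelection",
    "score_gene",
    "build_priority_table",
    "select_panel",
    "write_priority_table",
]

DEFAULT_OVERLAP_CAP = 3


@dataclass(frozen=True)
class PriorityRecord:
    """One scored gene: rubric components and their 0-5 total."""

    gene: GeneSymbol
    direct: int
    transcriptional: int
    overlap_points: int
    total: int

    def __post_init__(self) -> None:
        if self.direct not in (0, 1) or self.transcriptional not in (0, 1):
            raise ValueError("direct and transcriptional flags must be 0 or 1")
        if not 0 <= self.overlap_points <= 3:
            raise ValueError("overlap_points must be within 0..3")
        if self.total != self.direct + self.transcriptional + self.overlap_points:
            raise ValueError("total must equal the sum of its components")


@dataclass(frozen=True)
class PanelSelection:
    """Configuration for turning a scored table into a validation panel."""

    threshold: int = 3
    manual_excludes: tuple = ()
    manual_includes: tuple = ()
    anchor: Optional[GeneSymbol] = "MMP12"

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 5:
            raise ValueError(f"threshold must be within 0..5, got {self.threshold}")
        excludes = tuple(normalize_symbol(g) for g in self.manual_excludes)
        includes = tuple(normalize_symbol(g) for g in self.manual_includes)
        clash = set(excludes) & set(includes)
        if clash:
            raise ValueError(f"genes both included and excluded: {sorted(clash)}")
        object.__setattr__(self, "manual_excludes", excludes)
        object.__setattr__(self, "manual_includes", includes)
        if self.anchor is not None:
            object.__setattr__(self, "anchor", normalize_symbol(self.anchor))


def score_gene(
    direct: int,
    transcriptional: int,
    overlap_count: int,
    overlap_cap: int = DEFAULT_OVERLAP_CAP,
) -> int:
    """Total rubric score: direct + transcriptional + min(overlap_count, cap).

    Overlap with 1/2/>=3 annotation sets contributes 1/2/3 points under the
    default cap.  Monotone non-decreasing in every argument.
    """
    if direct not in (0, 1) or transcriptional not in (0, 1):
        raise ValueError("direct and transcriptional flags must be 0 or 1")
    if overlap_count < 0:
        raise ValueError(f"overlap_count must be >= 0, got {overlap_count}")
    return direct + transcriptional + min(overlap_count, overlap_cap)


def build_priority_table(
    interactions: Sequence[InteractionRecord],
    direct_targets: GeneSet,
    annotation_sets: Sequence[GeneSet],
    overlap_cap: int = DEFAULT_OVERLAP_CAP,
) -> List[PriorityRecord]:
    """Score every distinct target gene of a single-source interaction list.

    direct = 1 iff the gene is in ``direct_targets``; transcriptional = 1 iff
    any of its records carries the transcription-regulation mechanism;
    overlap points come from (capped) membership counts over the annotation
    sets.  The result is sorted by total descending, then direct, then
    transcriptional, then symbol ascending -- a total order, so ties are
    stable across runs.
    """
    if not interactions:
        raise ValueError("interactions must be non-empty")
    sources = {rec.source for rec in interactions}
    if len(sources) > 1:
        raise ValueError(f"interactions must share one source node, got {sorted(sources)}")

    genes: list = []
    transcriptional: Dict[str, bool] = {}
    for rec in interactions:
        if rec.target not in transcriptional:
            genes.append(rec.target)
            transcriptional[rec.target] = False
        if rec.mechanism is Mechanism.TRANSCRIPTION_REGULATION:
            transcriptional[rec.target] = True

    if annotation_sets:
        focus = GeneSet(name="targets", category="focus", members=frozenset(genes))
        counts = membership_counts(focus, annotation_sets)
    else:
        counts = {g: 0 for g in genes}

    records = []
    for gene in genes:
        direct = int(gene in direct_targets.members) if direct_targets is not None else 0
        trans = int(transcriptional[gene])
        overlap_points = min(counts[gene], overlap_cap)
        records.append(
            PriorityRecord(
                gene=gene,
                direct=direct,
                transcriptional=trans,
                overlap_points=overlap_points,
                total=score_gene(direct, trans, counts[gene], overlap_cap),
            )
        )
    records.sort(key=lambda r: (-r.total, -r.direct, -r.transcriptional, r.gene))
    return records


def select_panel(records: Sequence[PriorityRecord], selection: PanelSelection) -> frozenset:
    """Apply threshold + manual curation + anchor to a scored table.

    Included: genes with total >= threshold, minus manual excludes, plus
    manual includes and the anchor gene.  Returns the (possibly empty)
    frozenset of panel genes; wrap in a GeneSet for GMT export.
    """
    chosen = {r.gene for r in records if r.total >= selection.threshold}
    chosen -= set(selection.manual_excludes)
    chosen |= set(selection.manual_includes)
    if selection.anchor is not None:
        chosen.add(selection.anchor)
    return frozenset(chosen)


def write_priority_table(records: Sequence[PriorityRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("Gene\tDirect Effect\tTranscriptional Effect\tOverlappingGene\tTotal Score\n")
        for r in records:
            fh.write(f"{r.gene}\t{r.direct}\t{r.transcriptional}\t{r.overlap_points}\t{r.total}\n")
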