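"""Packaged reference fixtures: the published worked example, transcribed.

The files under ``netprior/data`` transcribe the study's printed tables --
the curated downstream-interaction list, the prioritization table, the
pathway enrichment gene lists, the qPCR fold-change table, and the upstream-
regulator reference -- plus clearly labelled synthetic stand-ins for
proprietary resources (annotation gene sets, pathway definitions, biomarker
catalog).  They let the whole pipeline run offline and serve as the ground
truth for reproduction tests.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Dict, List, Tuple

from .core import CausalEdge, GeneSet, GeneSetCollection, InteractionRecord
from . import io as npio

__all__ = [
    "data_path",
    "interaction_records",
    "supplement_records",
    "all_downstream_records",
    "direct_targets",
    "annotation_sets",
    "priority_reference",
    "pathway_collection",
    "expression_reference",
    "expression_changes",
    "causal_network",
    "regulator_reference",
    "gene_universe",
    "expected_directions",
    "biomarker_catalog_path",
    "enzyme_inhibition_percent",
    "PANEL_GENES",
    "COMPOUNDS",
]

#: The five lead inhibitors profiled in the study.
COMPOUNDS = ("C1", "C7", "C9", "C10", "C15")

#: The eight-gene pharmacodynamic panel (anchor target + seven downstream genes).
PANEL_GENES = frozenset(
    {"MMP12", "CD44", "ADAM9", "NFKBIA", "PSME3", "SPARCL1", "CCL15", "APOA1"}
)

#: Percent MMP12 enzyme inhibition of the six assayed derivatives at 50 uM.
enzyme_inhibition_percent: Dict[str, float] = {
    "C1": 32.9,
    "C2": 35.0,
    "C3": 23.5,
    "C4": 23.3,
    "C5": 11.5,
    "C6": 21.3,
}


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(str(resources.files(__package__) / "data" / name))


def interaction_records() -> List[InteractionRecord]:
    """The 40 printed curated downstream interactions of MMP12."""
    return npio.read_interaction_table(data_path("downstream_interactions.tsv"))


def supplement_records() -> List[InteractionRecord]:
    """Downstream genes from the priority table absent from the printed 40."""
    return npio.read_interaction_table(data_path("downstream_supplement.tsv"))


def all_downstream_records() -> List[InteractionRecord]:
    return interaction_records() + supplement_records()


def direct_targets() -> GeneSet:
    return GeneSet(
        name="direct_targets",
        category="direct",
        members=frozenset(npio.read_symbol_list(data_path("direct_targets.txt"))),
    )


def annotation_sets() -> GeneSetCollection:
    """Synthetic stand-ins for the four cancer-process gene sets."""
    return npio.read_gmt(data_path("annotation_sets.gmt"))


def priority_reference() -> List[Tuple[str, int, int, int, int]]:
    """Reference rows (gene, direct, transcriptional, overlap, total)."""
    rows = []
    with open(data_path("table2_priorities.tsv"), encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "Gene\t")):
                continue
            gene, direct, trans, overlap, total = line.rstrip("\n").split("\t")
            rows.append((gene, int(direct), int(trans), int(overlap), int(total)))
    return rows


def pathway_collection() -> GeneSetCollection:
    return npio.read_gmt(data_path("pathways.gmt"))


def expression_reference() -> List[dict]:
    """The printed fold-change table, percent/direction cells verbatim."""
    rows = []
    with open(data_path("expression_changes.tsv"), encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "Compound\t")):
                continue
            compound, gene, fc, percent, direction = line.rstrip("\n").split("\t")
            rows.append(
                {
                    "compound": compound,
                    "gene": gene,
                    "fold_change": float(fc),
                    "printed_percent": percent,
                    "printed_direction": direction,
                }
            )
    return rows


def expression_changes():
    """The reference fold changes as ExpressionChange objects."""
    from .expression import ExpressionChange

    return [
        ExpressionChange.from_fold_change(r["gene"], r["compound"], r["fold_change"])
        for r in expression_reference()
    ]


def causal_network() -> List[CausalEdge]:
    return npio.read_causal_edges(data_path("causal_network.tsv"))


def regulator_reference() -> List[dict]:
    """Reference regulator calls with consistency splits and z values."""
    rows = []
    with open(data_path("regulator_reference.tsv"), encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "regulator\t")):
                continue
            (
                regulator,
                category,
                targets,
                z,
                z_compounds,
                compounds,
                n_used,
                n_consistent,
                forced,
            ) = line.rstrip("\n").split("\t")
            rows.append(
                {
                    "regulator": regulator,
                    "category": category,
                    "targets": {
                        t.split(":")[0]: int(t.split(":")[1]) for t in targets.split(",")
                    },
                    "z": float(z),
                    "z_compounds": z_compounds.split(","),
                    "compounds": compounds.split(","),
                    "n_used": int(n_used),
                    "n_consistent": int(n_consistent),
                    "split_forced": bool(int(forced)),
                }
            )
    return rows


def gene_universe() -> frozenset:
    return frozenset(npio.read_symbol_list(data_path("universe.txt")))


def expected_directions() -> Dict[str, str]:
    out = {}
    with open(data_path("expected_directions.tsv"), encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "gene\t")):
                continue
            gene, expected = line.rstrip("\n").split("\t")
            out[gene] = expected
    return out


def biomarker_catalog_path() -> Path:
    return data_path("biomarker_catalog.tsv")
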