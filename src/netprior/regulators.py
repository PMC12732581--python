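"""Causal upstream-regulator inference from observed expression directions.

For a regulator with known signed target edges, each usable target (known
expected sign, non-flat observed direction) contributes a consistency term
s_i = expected_sign x observed_sign; the activation z-score is

    z = sum(s_i) / sqrt(n_used),

the unweighted form, bounded by |z| <= sqrt(n_used) with equality iff all
usable targets agree.  z > +2 calls the regulator activated, z < -2
inhibited (the paper's thresholds; configurable).  Statistical support comes
from a right-tailed hypergeometric overlap p-value between the regulator's
target set and the changed-gene list, and regulators are ranked by that
p-value.  A regulator predicted active can have its own transcript
suppressed -- the score reads downstream network behaviour, not the
regulator's own level -- so paradoxical calls are reported as-is.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .core import CausalEdge, GeneSet, GeneSymbol, ParseError, SchemaError, normalize_symbol
from .enrich import hypergeom_right_tail
from .expression import Direction, ExpressionChange

__all__ = [
    "RegulatorState",
    "ZScoreResult",
    "RegulatorCall",
    "activation_zscore",
    "overlap_pvalue",
    "call_regulators",
    "consensus_regulators",
    "annotate_biomarkers",
    "export_signature_network",
    "write_regulator_calls",
]


class RegulatorState(enum.Enum):
    ACTIVATED = "activated"
    INHIBITED = "inhibited"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ZScoreResult:
    z: float
    n_used: int
    n_consistent: int
    n_inconsistent: int


@dataclass(frozen=True)
class RegulatorCall:
    """One regulator's inferred state for one expression dataset."""

    regulator: str
    category: str
    n_used: int
    n_consistent: int
    n_inconsistent: int
    z: float
    p_overlap: float
    state: RegulatorState


def activation_zscore(
    edges: Sequence[CausalEdge],
    changes: Dict[GeneSymbol, int],
) -> ZScoreResult:
    """Unweighted activation z-score for one regulator.

    ``changes`` maps gene symbol to observed direction sign (+1/-1/0).
    Edges with expected_sign 0, targets absent from ``changes`` and targets
    with observed sign 0 are excluded from n_used.  Invariant to edge order.

    Raises
    ------
    ValueError
        If edges span several regulators, contain duplicate targets, or no
        edge is usable (no evidence).
    """
    regulators = {e.regulator for e in edges}
    if len(regulators) != 1:
        raise ValueError(f"edges must share one regulator, got {sorted(regulators)}")
    targets = [e.target for e in edges]
    if len(targets) != len(set(targets)):
        dupes = sorted({t for t in targets if targets.count(t) > 1})
        raise ValueError(f"duplicate target edges for {regulators.pop()!r}: {dupes}")

    total = 0
    n_used = n_consistent = 0
    for edge in edges:
        if edge.expected_sign == 0:
            continue
        observed = changes.get(edge.target, 0)
        if observed == 0:
            continue
        s = edge.expected_sign * (1 if observed > 0 else -1)
        total += s
        n_used += 1
        n_consistent += int(s > 0)
    if n_used == 0:
        raise ValueError(f"no usable evidence for regulator {next(iter(regulators))!r}")
    return ZScoreResult(
        z=total / math.sqrt(n_used),
        n_used=n_used,
        n_consistent=n_consistent,
        n_inconsistent=n_used - n_consistent,
    )


def overlap_pvalue(
    regulator_targets: Set[GeneSymbol],
    changed_genes: Set[GeneSymbol],
    universe: Set[GeneSymbol],
) -> float:
    """Right-tail hypergeometric probability of the target/changed overlap."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    targets = set(regulator_targets) & universe
    changed = set(changed_genes) & universe
    k = len(targets & changed)
    return hypergeom_right_tail(k=k, n=len(changed), K=len(targets), N=len(universe))


def changes_to_signs(changes: Sequence[ExpressionChange]) -> Dict[GeneSymbol, int]:
    """Observed direction signs (Up=+1, Dn=-1, nc=0) from expression calls."""
    return {c.gene: c.direction.sign for c in changes}


def call_regulators(
    network: Sequence[CausalEdge],
    changes: Sequence[ExpressionChange],
    universe: Set[GeneSymbol],
    p_max: float = 0.05,
    z_hi: float = 2.0,
    z_lo: float = -2.0,
    category_filter: Optional[Set[str]] = None,
) -> List[RegulatorCall]:
    """Score every regulator of the network against one expression dataset.

    One call per regulator with >= 1 usable edge, filtered to overlap
    p-value < ``p_max`` and optionally to a set of category tags; ranked by
    p ascending, ties by |z| descending then label.  No fold-change
    magnitude cutoff is applied: direction alone carries the evidence.
    """
    if not network:
        raise ValueError("causal network must be non-empty")
    signs = changes_to_signs(changes)
    changed = {g for g, s in signs.items() if s != 0}

    by_regulator: Dict[str, List[CausalEdge]] = {}
    for edge in network:
        by_regulator.setdefault(edge.regulator, []).append(edge)

    calls = []
    for regulator, edges in by_regulator.items():
        category = next((e.category for e in edges if e.category), "")
        if category_filter is not None and category not in category_filter:
            continue
        try:
            score = activation_zscore(edges, signs)
        except ValueError:
            continue  # no usable evidence for this dataset
        targets = {e.target for e in edges}
        p = overlap_pvalue(targets, changed, universe)
        if p >= p_max:
            continue
        if score.z > z_hi:
            state = RegulatorState.ACTIVATED
        elif score.z < z_lo:
            state = RegulatorState.INHIBITED
        else:
            state = RegulatorState.INDETERMINATE
        calls.append(
            RegulatorCall(
                regulator=regulator,
                category=category,
                n_used=score.n_used,
                n_consistent=score.n_consistent,
                n_inconsistent=score.n_inconsistent,
                z=score.z,
                p_overlap=p,
                state=state,
            )
        )
    calls.sort(key=lambda c: (c.p_overlap, -abs(c.z), c.regulator))
    return calls


def consensus_regulators(
    calls_by_compound: Dict[str, Sequence[RegulatorCall]],
) -> List[dict]:
    """Group regulator calls across compounds.

    Returns one row per regulator with the compounds in which it was called,
    tagged ``shared`` when present in >= 2 compounds and ``unique``
    otherwise, sorted by (descending compound count, label).
    """
    if not calls_by_compound:
        raise ValueError("need calls for at least one compound")
    grouped: Dict[str, List[Tuple[str, RegulatorCall]]] = {}
    for compound in sorted(calls_by_compound):
        for call in calls_by_compound[compound]:
            grouped.setdefault(call.regulator, []).append((compound, call))
    rows = []
    for regulator in sorted(grouped):
        entries = grouped[regulator]
        compounds = [c for c, _ in entries]
        rows.append(
            {
                "regulator": regulator,
                "compounds": compounds,
                "status": "shared" if len(compounds) >= 2 else "unique",
                "z_by_compound": {c: call.z for c, call in entries},
            }
        )
    rows.sort(key=lambda r: (-len(r["compounds"]), r["regulator"]))
    return rows


def annotate_biomarkers(
    panel: GeneSet,
    catalog_path,
    species: str = "Homo sapiens",
    disease: str = "cancer",
    context: str = "lung cancer cell lines",
) -> Dict[GeneSymbol, Optional[List[str]]]:
    """Left-join panel genes against a biomarker catalog TSV.

    The catalog has columns ``gene``, ``species``, ``disease``, ``context``,
    ``biomarker_roles`` (roles ';'-separated).  Rows failing the species/
    disease/context filters are excluded from the join; panel genes with no
    surviving row map to None.
    """
    rows = []
    with open(catalog_path, "r", encoding="utf-8", newline="") as fh:
        lines = [l for l in fh if l.strip() and not l.lstrip().startswith("#")]
    if not lines:
        raise SchemaError(f"{catalog_path}: empty biomarker catalog")
    header = [h.strip().lower() for h in lines[0].rstrip("\n").split("\t")]
    required = ["gene", "species", "disease", "context", "biomarker_roles"]
    for col in required:
        if col not in header:
            raise SchemaError(f"{catalog_path}: missing required column {col!r}")
    idx = {col: header.index(col) for col in required}
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.rstrip("\n").split("\t")
        if len(fields) < len(header):
            raise ParseError(f"{catalog_path}:{lineno}: expected {len(header)} fields")
        rows.append({col: fields[i].strip() for col, i in idx.items()})

    def keep(row: dict) -> bool:
        return (
            row["species"].lower() == species.lower()
            and row["disease"].lower() == disease.lower()
            and row["context"].lower() == context.lower()
        )

    annotation: Dict[GeneSymbol, Optional[List[str]]] = {g: None for g in sorted(panel.members)}
    for row in rows:
        if not keep(row):
            continue
        gene = normalize_symbol(row["gene"])
        if gene in annotation:
            roles = [r.strip() for r in row["biomarker_roles"].split(";") if r.strip()]
            annotation[gene] = sorted(set(roles) | set(annotation[gene] or []))
    return annotation


def export_signature_network(
    edges: Sequence[CausalEdge],
    changes: Sequence[ExpressionChange],
    sif_path,
    node_attr_path,
    edge_attr_path,
) -> None:
    """Write the signature network as SIF plus node/edge attribute TSVs.

    Nodes carry the observed direction from ``changes`` (red-up/green-down
    in the field's usual rendering); edges carry their expected sign.
    Line order is deterministic (sorted).
    """
    relation = {1: "activates", -1: "inhibits", 0: "regulates"}
    sif_lines = sorted(
        (e.regulator, relation[e.expected_sign], e.target) for e in edges
    )
    with open(sif_path, "w", encoding="utf-8", newline="") as fh:
        for line in sif_lines:
            fh.write("\t".join(line) + "\n")
    directions = {c.gene: c.direction.value for c in changes}
    with open(node_attr_path, "w", encoding="utf-8", newline="") as fh:
        fh.write("node\tdirection\n")
        for gene in sorted(directions):
            fh.write(f"{gene}\t{directions[gene]}\n")
    with open(edge_attr_path, "w", encoding="utf-8", newline="") as fh:
        fh.write("regulator\ttarget\texpected_sign\n")
        for e in sorted(edges, key=lambda e: (e.regulator, e.target)):
            fh.write(f"{e.regulator}\t{e.target}\t{e.expected_sign:+d}\n")


def write_regulator_calls(calls: Sequence[RegulatorCall], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("regulator\tcategory\tn_used\tn_consistent\tn_inconsistent\tz\tp_overlap\tstate\n")
        for c in calls:
            fh.write(
                f"{c.regulator}\t{c.category}\t{c.n_used}\t{c.n_consistent}\t"
                f"{c.n_inconsistent}\t{c.z:+.2f}\t{c.p_overlap:.6g}\t{c.state.value}\n"
            )
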