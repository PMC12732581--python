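"""qPCR delta-Ct arithmetic, fold-change calls, and assay summary arithmetic.

Relative quantification follows the standard comparative-Ct scheme: per
sample, the target gene's cycle threshold is normalized to a housekeeping
gene (delta-Ct = Ct_gene - Ct_housekeeping); basal abundance is 2^-dCt and
the treated-vs-control fold change is 2^-ddCt.  Percent change is
(FC - 1) x 100, reported rounded to the nearest integer, with direction Up /
Dn / nc exactly at FC = 1.  Replicates are aggregated by mean Ct within
(gene, group) by default; per-replicate fold changes combined by geometric
mean are available as a config choice (the two coincide for balanced
designs, which is why mean-Ct is the default).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import CtMatrix, GeneSymbol, ODPlate, normalize_symbol

__all__ = [
    "Direction",
    "ExpressionChange",
    "BasalExpression",
    "ValidationIssue",
    "delta_ct",
    "basal_expression",
    "fold_change_ddct",
    "percent_and_direction",
    "format_percent",
    "viability_percent",
    "plate_viability",
    "summarize_inhibition",
    "ct_matrix_fold_changes",
    "ct_matrix_basal",
    "validate_printed_percent",
    "write_expression_table",
]


class Direction(enum.Enum):
    UP = "Up"
    DN = "Dn"
    NC = "nc"

    @property
    def sign(self) -> int:
        return {"Up": 1, "Dn": -1, "nc": 0}[self.value]

    @classmethod
    def parse(cls, token: str) -> "Direction":
        key = token.strip().lower()
        for member in cls:
            if member.value.lower() == key:
                return member
        raise ValueError(f"unknown direction token {token!r}")


@dataclass(frozen=True)
class ExpressionChange:
    """Per-gene, per-compound fold change with derived percent and direction."""

    gene: GeneSymbol
    compound: str
    fold_change: float
    percent_change: int
    direction: Direction

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_symbol(self.gene))
        if self.fold_change <= 0:
            raise ValueError(f"fold change must be positive, got {self.fold_change}")

    @classmethod
    def from_fold_change(cls, gene: str, compound: str, fold_change: float) -> "ExpressionChange":
        percent, direction = percent_and_direction(fold_change)
        return cls(
            gene=gene,
            compound=compound,
            fold_change=fold_change,
            percent_change=percent,
            direction=direction,
        )


@dataclass(frozen=True)
class BasalExpression:
    """Housekeeping-normalized basal abundance, 2^-dCt."""

    gene: GeneSymbol
    sample: str
    value: float

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("basal expression must be positive")


@dataclass(frozen=True)
class ValidationIssue:
    """A data-consistency warning attached to an input row (never fatal)."""

    compound: str
    gene: str
    message: str


def delta_ct(ct_gene: float, ct_housekeeping: float) -> float:
    """dCt = Ct_gene - Ct_housekeeping; NaN inputs propagate as NaN."""
    if ct_gene is None or ct_housekeeping is None:
        return math.nan
    return float(ct_gene) - float(ct_housekeeping)


def basal_expression(dct: float) -> float:
    """Basal abundance 2^-dCt (dimensionless, relative to housekeeping)."""
    if not math.isfinite(dct):
        raise ValueError(f"delta-Ct must be finite, got {dct}")
    return 2.0 ** (-dct)


def fold_change_ddct(dct_treated: float, dct_control: float) -> float:
    """Fold change 2^-(dCt_treated - dCt_control)."""
    if not (math.isfinite(dct_treated) and math.isfinite(dct_control)):
        return math.nan
    return 2.0 ** (-(dct_treated - dct_control))


def percent_and_direction(fold_change: float) -> Tuple[int, Direction]:
    """Percent change (FC - 1) x 100 rounded to the nearest integer, and call.

    Direction is Up for FC > 1, Dn for FC < 1, nc at exactly 1.
    """
    if not math.isfinite(fold_change) or fold_change <= 0:
        raise ValueError(f"fold change must be positive and finite, got {fold_change}")
    percent = round((fold_change - 1.0) * 100.0)
    if fold_change > 1.0:
        direction = Direction.UP
    elif fold_change < 1.0:
        direction = Direction.DN
    else:
        direction = Direction.NC
    return int(percent), direction


def format_percent(percent: int) -> str:
    """Report-style percent with sign and thousands separators, e.g. +26,680%."""
    return f"{percent:+,d}%"


def viability_percent(od_treated: float, od_untreated: float) -> float:
    """Cell viability % = 100 x OD_treated / OD_untreated."""
    if od_untreated <= 0:
        raise ValueError(f"untreated-control OD must be positive, got {od_untreated}")
    return 100.0 * od_treated / od_untreated


def plate_viability(plate: ODPlate) -> Dict[str, float]:
    """Mean viability % per treated group against the control-group mean OD."""
    control_mean = float(np.mean(plate.readings[plate.control_group]))
    return {
        group: float(np.mean([viability_percent(v, control_mean) for v in values]))
        for group, values in plate.readings.items()
        if group != plate.control_group
    }


def summarize_inhibition(values: Sequence[float]) -> Tuple[float, float, float]:
    """(mean rounded to 1 decimal, min, max) of percent-inhibition values."""
    values = list(values)
    if not values:
        raise ValueError("need at least one inhibition value")
    return (round(float(np.mean(values)), 1), min(values), max(values))


def _group_dct(ctm: CtMatrix, gene: str, group: str, aggregation: str) -> float:
    """Aggregate a gene's dCt over a group's replicate samples."""
    idx = ctm.sample_indices(group)
    if not idx:
        raise ValueError(f"no samples in group {group!r}")
    gene_ct = ctm.row(gene)[idx]
    hk_ct = ctm.row(ctm.housekeeping)[idx]
    dcts = gene_ct - hk_ct
    dcts = dcts[~np.isnan(dcts)]
    if dcts.size == 0:
        return math.nan
    if aggregation not in ("mean_ct", "per_replicate_geomean"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    # mean of per-replicate dCt == (mean gene Ct) - (mean hk Ct) for paired
    # wells, and the geometric mean of per-replicate 2^-ddCt is 2^-(mean ddCt),
    # so both config choices reduce to the mean dCt here.
    return float(np.mean(dcts))


def ct_matrix_fold_changes(
    ctm: CtMatrix,
    control_group: str,
    aggregation: str = "mean_ct",
    genes: Optional[Sequence[str]] = None,
) -> List[ExpressionChange]:
    """Treated-vs-control fold changes for every (gene, treated group).

    The compound label of each change is taken from the group's samples
    (falling back to the group name).  The housekeeping gene itself is not
    reported.
    """
    if control_group not in ctm.groups:
        raise ValueError(f"control group {control_group!r} not present in matrix")
    wanted = [normalize_symbol(g) for g in genes] if genes else list(ctm.genes)
    changes = []
    for group in ctm.groups:
        if group == control_group:
            continue
        compound = next(
            (s.compound for s in ctm.samples if s.group == group and s.compound), group
        )
        for gene in wanted:
            if gene == ctm.housekeeping:
                continue
            fc = fold_change_ddct(
                _group_dct(ctm, gene, group, aggregation),
                _group_dct(ctm, gene, control_group, aggregation),
            )
            if math.isnan(fc):
                continue
            changes.append(ExpressionChange.from_fold_change(gene, compound, fc))
    return changes


def ct_matrix_basal(ctm: CtMatrix, gene: str) -> List[BasalExpression]:
    """Per-group basal expression 2^-dCt of one gene (mean-Ct aggregation)."""
    out = []
    for group in ctm.groups:
        dct = _group_dct(ctm, gene, group, "mean_ct")
        if math.isfinite(dct):
            out.append(BasalExpression(gene=normalize_symbol(gene), sample=group, value=basal_expression(dct)))
    return out


def validate_printed_percent(
    changes: Sequence[ExpressionChange],
    printed: Dict[Tuple[str, str], Tuple[str, str]],
) -> List[ValidationIssue]:
    """Check printed percent/direction cells against the (FC-1)x100 rule.

    ``printed`` maps (compound, gene) to the raw printed (percent, direction)
    strings.  Inconsistent cells are flagged, never corrected: the printed
    value stays authoritative in the source table and the issue list is the
    audit trail.
    """
    issues = []
    for change in changes:
        key = (change.compound, change.gene)
        if key not in printed:
            continue
        printed_percent, printed_direction = printed[key]
        cleaned = printed_percent.replace(",", "").replace("%", "").replace("−", "-").strip()
        try:
            printed_value = float(cleaned)
        except ValueError:
            issues.append(ValidationIssue(*key, f"unparseable percent cell {printed_percent!r}"))
            continue
        if round(printed_value) != change.percent_change:
            issues.append(
                ValidationIssue(
                    *key,
                    f"printed percent {printed_percent!r} disagrees with "
                    f"(FC-1)x100 = {format_percent(change.percent_change)} "
                    f"for fold change {change.fold_change}",
                )
            )
        if printed_direction and Direction.parse(printed_direction) is not change.direction:
            issues.append(
                ValidationIssue(
                    *key,
                    f"printed direction {printed_direction!r} disagrees with "
                    f"fold change {change.fold_change}",
                )
            )
    return issues


def write_expression_table(changes: Sequence[ExpressionChange], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("Compound\tGene\tFold Change\t% Change\tDirection\n")
        for c in changes:
            fh.write(
                f"{c.compound}\t{c.gene}\t{c.fold_change:.2f}\t"
                f"{format_percent(c.percent_change)}\t{c.direction.value}\n"
            )
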