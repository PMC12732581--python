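"""Domain model for the MMP12 downstream-network analysis.

Everything downstream of this module speaks in terms of a handful of small
value types: curated interaction records (one edge from the inhibited target
to a downstream gene, annotated with effect and mechanism), named gene sets,
signed causal regulator->target edges, qPCR cycle-threshold matrices, and
optical-density plates.  Gene identity is a normalized HGNC-style symbol:
uppercase, whitespace-trimmed, and never alias-remapped -- curated exports
contain legacy tokens (e.g. ``NID``) that are preserved verbatim.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "NetpriorError",
    "InvalidSymbolError",
    "SchemaError",
    "ParseError",
    "Effect",
    "Mechanism",
    "GeneSymbol",
    "normalize_symbol",
    "InteractionRecord",
    "GeneSet",
    "GeneSetCollection",
    "CausalEdge",
    "Sample",
    "CtMatrix",
    "ODPlate",
    "filter_interactions",
]


class NetpriorError(Exception):
    """Base class for all errors raised by this package."""


class InvalidSymbolError(NetpriorError, ValueError):
    """A gene symbol is empty or contains internal whitespace."""


class SchemaError(NetpriorError, ValueError):
    """A tabular input is missing a required column."""


class ParseError(NetpriorError, ValueError):
    """A tabular input contains a malformed row; message names the line."""


# A normalized gene symbol is just a string; the alias documents intent.
GeneSymbol = str


def normalize_symbol(raw: str) -> GeneSymbol:
    """Normalize a raw gene token to an HGNC-style symbol.

    Trims surrounding whitespace and uppercases.  No alias remapping is
    performed: legacy tokens are kept exactly as printed in the source.
    Idempotent: ``normalize_symbol(normalize_symbol(x)) == normalize_symbol(x)``.

    Raises
    ------
    InvalidSymbolError
        If the token is empty after trimming or contains internal whitespace.
    """
    if raw is None:
        raise InvalidSymbolError("gene symbol is None")
    token = raw.strip()
    if not token:
        raise InvalidSymbolError(f"empty gene symbol: {raw!r}")
    token = token.upper()
    if any(ch.isspace() for ch in token):
        raise InvalidSymbolError(f"gene symbol contains internal whitespace: {raw!r}")
    return token


class Effect(enum.Enum):
    """Directional effect of a curated interaction."""

    ACTIVATION = "activation"
    INHIBITION = "inhibition"
    UNSPECIFIED = "unspecified"

    @classmethod
    def parse(cls, token: str) -> "Effect":
        return _parse_enum(cls, token)


class Mechanism(enum.Enum):
    """Mechanism of a curated interaction (proteolytic vs transcriptional)."""

    CLEAVAGE = "cleavage"
    TRANSCRIPTION_REGULATION = "transcription_regulation"
    UNSPECIFIED = "unspecified"

    @classmethod
    def parse(cls, token: str) -> "Mechanism":
        return _parse_enum(cls, token)


def _parse_enum(cls, token: str):
    key = token.strip().lower().replace(" ", "_").replace("-", "_")
    for member in cls:
        if member.value == key:
            return member
    valid = ", ".join(m.value for m in cls)
    raise ParseError(f"unknown {cls.__name__.lower()} token {token!r}; expected one of: {valid}")


@dataclass(frozen=True)
class InteractionRecord:
    """One curated edge from the source protein to a downstream target gene."""

    source: GeneSymbol
    object_name: str
    target: GeneSymbol
    effect: Effect
    mechanism: Mechanism

    def __post_init__(self) -> None:
        object.__setattr__(self, "source", normalize_symbol(self.source))
        object.__setattr__(self, "target", normalize_symbol(self.target))
        if not isinstance(self.effect, Effect):
            object.__setattr__(self, "effect", Effect.parse(str(self.effect)))
        if not isinstance(self.mechanism, Mechanism):
            object.__setattr__(self, "mechanism", Mechanism.parse(str(self.mechanism)))


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols with a free-text category tag."""

    name: str
    category: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ValueError("gene set name must be non-empty")
        members = frozenset(normalize_symbol(m) for m in self.members)
        if not members:
            raise ValueError(f"gene set {self.name!r} must have at least one member")
        object.__setattr__(self, "members", members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


@dataclass(frozen=True)
class GeneSetCollection:
    """An ordered collection of gene sets with pairwise-distinct names."""

    sets: tuple = ()
    universe: Optional[frozenset] = None

    def __post_init__(self) -> None:
        sets = tuple(self.sets)
        names = [s.name for s in sets]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate gene set names: {sorted(dupes)}")
        object.__setattr__(self, "sets", sets)
        if self.universe is not None:
            universe = frozenset(normalize_symbol(g) for g in self.universe)
            for s in sets:
                stray = s.members - universe
                if stray:
                    raise ValueError(
                        f"set {s.name!r} has members outside the universe: {sorted(stray)[:5]}"
                    )
            object.__setattr__(self, "universe", universe)

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list:
        return [s.name for s in self.sets]

    def union_members(self) -> frozenset:
        out: set = set()
        for s in self.sets:
            out |= s.members
        return frozenset(out)


@dataclass(frozen=True)
class CausalEdge:
    """A signed regulator->target edge.

    ``regulator`` may be a plain symbol or an opaque complex/family label
    ("SMAD2/3/4 complex", "AKT family"); such labels are stored verbatim and
    never split.  ``expected_sign`` is +1 if activation of the regulator is
    expected to increase the target, -1 if to decrease it, 0 if unknown.
    """

    regulator: str
    target: GeneSymbol
    expected_sign: int
    category: str = ""

    def __post_init__(self) -> None:
        reg = self.regulator.strip() if isinstance(self.regulator, str) else ""
        if not reg:
            raise ValueError("regulator label must be non-empty")
        object.__setattr__(self, "regulator", reg)
        object.__setattr__(self, "target", normalize_symbol(self.target))
        if self.expected_sign not in (-1, 0, 1):
            raise ValueError(f"expected_sign must be -1, 0 or +1; got {self.expected_sign!r}")


@dataclass(frozen=True)
class Sample:
    """One qPCR sample: a well/replicate with its group and compound labels."""

    sample_id: str
    group: str
    compound: str = ""


@dataclass
class CtMatrix:
    """A gene x sample matrix of qPCR cycle-threshold values.

    Missing measurements are NaN.  The housekeeping gene must be one of the
    rows; it is the normalization reference for the delta-Ct arithmetic.
    """

    genes: list
    samples: list
    ct: np.ndarray
    housekeeping: GeneSymbol

    def __post_init__(self) -> None:
        self.genes = [normalize_symbol(g) for g in self.genes]
        self.housekeeping = normalize_symbol(self.housekeeping)
        self.ct = np.asarray(self.ct, dtype=float)
        if self.ct.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"ct shape {self.ct.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if self.housekeeping not in self.genes:
            raise ValueError(f"housekeeping gene {self.housekeeping!r} not among genes")
        with np.errstate(invalid="ignore"):
            if np.isinf(self.ct).any():
                raise ValueError("ct values must be finite where present (use NaN for missing)")

    def row(self, gene: GeneSymbol) -> np.ndarray:
        return self.ct[self.genes.index(normalize_symbol(gene))]

    def sample_indices(self, group: str) -> list:
        return [i for i, s in enumerate(self.samples) if s.group == group]

    @property
    def groups(self) -> list:
        seen: list = []
        for s in self.samples:
            if s.group not in seen:
                seen.append(s.group)
        return seen


@dataclass
class ODPlate:
    """Optical-density readings grouped by treatment condition."""

    readings: dict
    control_group: str = "untreated"

    def __post_init__(self) -> None:
        if self.control_group not in self.readings:
            raise ValueError(f"control group {self.control_group!r} missing from plate")
        for group, values in self.readings.items():
            values = list(values)
            if not values:
                raise ValueError(f"group {group!r} has no readings")
            if any(v <= 0 for v in values):
                raise ValueError(f"group {group!r} has non-positive optical densities")
            self.readings[group] = values


def filter_interactions(
    records: Sequence[InteractionRecord],
    effect: Optional[Effect] = None,
    mechanism: Optional[Mechanism] = None,
) -> list:
    """Subset interaction records by effect and/or mechanism (conjunctive).

    Preserves input order; an empty result is allowed.  With no filters the
    input is returned unchanged (as a new list).
    """
    out = []
    for rec in records:
        if effect is not None and rec.effect is not effect:
            continue
        if mechanism is not None and rec.mechanism is not mechanism:
            continue
        out.append(rec)
    return out
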