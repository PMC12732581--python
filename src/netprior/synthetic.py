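"""Seeded generators for every pipeline input, with planted ground truth.

The generators emulate the study's data sources -- curated gene-set
collections with controlled overlap structure, signed causal
regulator->target networks with planted active/inhibited/null regulators,
and qPCR Ct matrices with planted fold changes -- so that the full pipeline
is testable offline.  Every planted quantity is emitted in a machine-
readable truth ledger; recovery tests consume the ledger, never the
generator's internals.  All generators are pure functions of (spec, seed).

The qPCR noise model is Gaussian on the cycle-threshold scale (hence
multiplicative on expression), default sd 0.2 cycles per well, applied to
target-gene rows; the housekeeping row is the deterministic reference
(reference variability is subsumed into the per-gene noise term).  The
default replicate structure mirrors the study design: three independent
experiments with duplicate wells each, i.e. six wells per (gene, group).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import CausalEdge, CtMatrix, GeneSet, GeneSetCollection, ODPlate, Sample
from .expression import Direction, ExpressionChange

__all__ = [
    "SetSpec",
    "RegulatorSpec",
    "SyntheticSpec",
    "gen_universe",
    "gen_gene_sets",
    "gen_causal_network",
    "gen_ct_matrix",
    "gen_od_plate",
]


@dataclass(frozen=True)
class SetSpec:
    """One synthetic gene set: name, total size and a category tag."""

    name: str
    size: int
    category: str = "process"


@dataclass(frozen=True)
class RegulatorSpec:
    """One synthetic regulator with its planted truth.

    ``true_state``: "active", "inhibited" or "null".  ``consistency`` is the
    probability that a target's observed direction agrees with the planted
    state; for a null regulator observed directions are fair coins.
    """

    label: str
    n_targets: int
    true_state: str = "active"
    consistency: float = 1.0

    def __post_init__(self) -> None:
        if self.true_state not in ("active", "inhibited", "null"):
            raise ValueError(f"unknown true_state {self.true_state!r}")
        if not 0.0 <= self.consistency <= 1.0:
            raise ValueError("consistency must lie in [0, 1]")
        if self.n_targets <= 0:
            raise ValueError("each regulator needs at least one target")


@dataclass(frozen=True)
class SyntheticSpec:
    """Complete configuration for one synthetic dataset."""

    seed: int = 0
    universe_size: int = 200
    set_specs: tuple = ()
    overlap_design: Optional[dict] = None  # signature tuple -> planted count
    regulator_specs: tuple = ()
    ct_noise_sd: float = 0.2
    planted_fold_changes: Optional[dict] = None  # group -> {gene: FC}
    n_experiments: int = 3
    n_technical: int = 2
    housekeeping: str = "GAPDH"

    def __post_init__(self) -> None:
        if self.universe_size < 1:
            raise ValueError("universe_size must be >= 1")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        for s in self.set_specs:
            if s.size > self.universe_size:
                raise ValueError(f"set {s.name!r} larger than the universe")


def gen_universe(size: int) -> List[str]:
    """Deterministic universe of symbols G0001..; seed-independent by design

    (randomness enters at later stages, so two specs with different seeds
    share a universe of the same size).
    """
    if size < 1:
        raise ValueError("universe size must be >= 1")
    width = max(4, len(str(size)))
    return [f"G{i:0{width}d}" for i in range(1, size + 1)]


def gen_gene_sets(
    spec: SyntheticSpec, universe: Sequence[str]
) -> Tuple[GeneSetCollection, dict]:
    """Build gene sets with exactly the planted overlap structure.

    Partition-first allocation: each gene is assigned one Venn signature
    (from ``overlap_design``, a map signature-tuple -> count over the k sets
    of ``set_specs``), then sets are collected from the signatures; remaining
    capacity of each set is filled with exclusive genes.  This guarantees
    exact planted overlaps.  The truth ledger records each placed gene's
    signature and the per-set membership.
    """
    if not spec.set_specs:
        raise ValueError("set_specs must be non-empty")
    k = len(spec.set_specs)
    design = dict(spec.overlap_design or {})
    for signature in design:
        if len(signature) != k or not any(signature):
            raise ValueError(f"bad signature {signature!r} for {k} sets")

    # exclusive fill per set = declared size minus planted multi-set load
    load = [0] * k
    for signature, count in design.items():
        for i, bit in enumerate(signature):
            if bit:
                load[i] += count
    for i, s in enumerate(spec.set_specs):
        if load[i] > s.size:
            raise ValueError(
                f"infeasible overlap design: set {s.name!r} needs {load[i]} "
                f"shared genes but has size {s.size}"
            )
        exclusive = s.size - load[i]
        signature = tuple(j == i for j in range(k))
        design[signature] = design.get(signature, 0) + exclusive

    total = sum(design.values())
    if total > len(universe):
        raise ValueError(
            f"infeasible overlap design: needs {total} genes, universe has {len(universe)}"
        )

    rng = np.random.default_rng(spec.seed)
    pool = list(universe)
    rng.shuffle(pool)
    members: List[set] = [set() for _ in range(k)]
    signature_of: Dict[str, tuple] = {}
    cursor = 0
    for signature in sorted(design, reverse=True):
        for gene in pool[cursor : cursor + design[signature]]:
            signature_of[gene] = signature
            for i, bit in enumerate(signature):
                if bit:
                    members[i].add(gene)
        cursor += design[signature]

    sets = tuple(
        GeneSet(name=s.name, category=s.category, members=frozenset(members[i]))
        for i, s in enumerate(spec.set_specs)
    )
    ledger = {
        "signature_of": signature_of,
        "set_sizes": {s.name: len(members[i]) for i, s in enumerate(spec.set_specs)},
        "signature_counts": {sig: n for sig, n in design.items() if n},
    }
    return GeneSetCollection(sets=sets), ledger


def gen_causal_network(
    spec: SyntheticSpec, universe: Sequence[str]
) -> Tuple[List[CausalEdge], List[ExpressionChange], dict]:
    """Signed causal network with planted regulator states.

    Each regulator receives ``n_targets`` edges with random expected signs;
    target pools are disjoint across regulators so one coherent observed
    change list exists.  Observed direction of a target: for an active
    (inhibited) regulator it agrees with (opposes) the expected sign with
    probability ``consistency``; for a null regulator it is a fair coin.
    Returns (edges, observed changes, truth ledger).
    """
    if not spec.regulator_specs:
        raise ValueError("regulator_specs must be non-empty")
    needed = sum(r.n_targets for r in spec.regulator_specs)
    if needed > len(universe):
        raise ValueError(f"regulators need {needed} targets, universe has {len(universe)}")
    rng = np.random.default_rng(spec.seed)
    pool = list(universe)
    rng.shuffle(pool)

    edges: List[CausalEdge] = []
    changes: List[ExpressionChange] = []
    truth: Dict[str, dict] = {}
    cursor = 0
    for reg in spec.regulator_specs:
        targets = pool[cursor : cursor + reg.n_targets]
        cursor += reg.n_targets
        expected = rng.choice([-1, 1], size=reg.n_targets)
        state_sign = {"active": 1, "inhibited": -1, "null": 0}[reg.true_state]
        observed = []
        for e in expected:
            if state_sign == 0:
                obs = int(rng.choice([-1, 1]))
            else:
                agree = rng.random() < reg.consistency
                obs = int(e) * state_sign * (1 if agree else -1)
            observed.append(obs)
        for target, e, obs in zip(targets, expected, observed):
            edges.append(
                CausalEdge(regulator=reg.label, target=target, expected_sign=int(e))
            )
            fc = 2.0 if obs > 0 else 0.5  # magnitude is irrelevant to the score
            changes.append(ExpressionChange.from_fold_change(target, "synthetic", fc))
        truth[reg.label] = {
            "true_state": reg.true_state,
            "targets": list(targets),
            "expected_signs": [int(e) for e in expected],
            "observed_signs": observed,
        }
    return edges, changes, truth


def gen_ct_matrix(
    spec: SyntheticSpec,
    genes: Sequence[str],
    treated_groups: Sequence[str],
    control_group: str = "untreated",
    baseline_dct: float = 5.0,
    housekeeping_ct: float = 18.0,
) -> Tuple[CtMatrix, dict]:
    """Ct matrix with planted fold changes and Gaussian cycle noise.

    Control wells sit at the per-gene baseline dCt; treated wells add the
    planted -log2(FC) shift for their group (``spec.planted_fold_changes``
    maps group -> {gene: FC}); every target-gene well then receives
    N(0, ct_noise_sd) noise.  Wells per group = n_experiments x n_technical.
    The housekeeping row is constant at ``housekeeping_ct``.
    """
    planted = {g: dict(v) for g, v in (spec.planted_fold_changes or {}).items()}
    for group in planted:
        if group not in treated_groups:
            raise ValueError(f"planted group {group!r} not among treated_groups")
    rng = np.random.default_rng(spec.seed)
    all_genes = list(genes)
    if spec.housekeeping not in all_genes:
        all_genes.append(spec.housekeeping)

    samples: List[Sample] = []
    groups = [control_group, *treated_groups]
    for group in groups:
        compound = "" if group == control_group else group
        for exp in range(1, spec.n_experiments + 1):
            for tech in range(1, spec.n_technical + 1):
                samples.append(
                    Sample(sample_id=f"{group}_e{exp}t{tech}", group=group, compound=compound)
                )

    n_wells = len(samples)
    ct = np.empty((len(all_genes), n_wells))
    for gi, gene in enumerate(all_genes):
        if gene == spec.housekeeping:
            ct[gi, :] = housekeeping_ct
            continue
        for si, sample in enumerate(samples):
            shift = 0.0
            fc = planted.get(sample.group, {}).get(gene)
            if fc is not None:
                shift = -math.log2(fc)
            noise = rng.normal(0.0, spec.ct_noise_sd) if spec.ct_noise_sd > 0 else 0.0
            ct[gi, si] = housekeeping_ct + baseline_dct + shift + noise

    matrix = CtMatrix(
        genes=all_genes, samples=samples, ct=ct, housekeeping=spec.housekeeping
    )
    ledger = {
        "planted_fold_changes": planted,
        "baseline_dct": baseline_dct,
        "control_group": control_group,
        "wells_per_group": spec.n_experiments * spec.n_technical,
    }
    return matrix, ledger


def gen_od_plate(
    planted_viability: Dict[str, float],
    seed: int,
    control_mean: float = 1.0,
    noise_cv: float = 0.05,
    n_wells: int = 6,
    control_group: str = "untreated",
) -> Tuple[ODPlate, dict]:
    """OD plate with planted per-group viability fractions (0-1 scale).

    Readings carry multiplicative lognormal-ish noise with coefficient of
    variation ``noise_cv``.
    """
    rng = np.random.default_rng(seed)

    def wells(mean: float) -> List[float]:
        return [float(mean * (1.0 + rng.normal(0.0, noise_cv))) for _ in range(n_wells)]

    readings = {control_group: wells(control_mean)}
    for group, viability in planted_viability.items():
        if not 0 < viability:
            raise ValueError(f"planted viability for {group!r} must be positive")
        readings[group] = wells(control_mean * viability)
    plate = ODPlate(readings=readings, control_group=control_group)
    return plate, {"planted_viability": dict(planted_viability)}
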