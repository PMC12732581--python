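# Methods

This note documents the models, parameters, numerical choices and known
limitations of the netprior pipeline. It states nothing the tests or the
acceptance script do not themselves compute.

## Problem setting

A single protein target (MMP12, macrophage metalloelastase) is inhibited
pharmacologically in NSCLC cells. The pipeline answers four questions:
which of the target's curated downstream genes are worth measuring; which
pathways the chosen panel touches; how strongly each panel gene responds
(qPCR); and which upstream regulators best explain the observed response
pattern. The deliverable is an eight-gene pharmacodynamic signature whose
directional behaviour separates on-target engagement (anchor gene down)
from adaptive escape (ADAM9 up).

## Data model and normalization

Gene identity is an uppercase, whitespace-trimmed HGNC-style symbol.
Normalization is deliberately *not* an alias service: legacy tokens in
curated exports (e.g. `NID`, `SERPINA10`) are preserved verbatim, because
silently remapping symbols would detach the artifact from its source table;
curation is the user's decision. Complex/family regulator labels
("SMAD2/3/4 complex", "AKT family") are opaque node identifiers and are
never split into members.

Interaction records carry an effect (activation / inhibition / unspecified)
and a mechanism (cleavage / transcription regulation / unspecified), parsed
case-insensitively from the enum vocabulary; free text does not pass the
parser. Duplicate (source, target, mechanism) rows collapse to one with a
logged warning — curated exports commonly repeat edges, and failing hard
would make real-world files unusable.

All interchange formats are plain text: tab-separated tables with `#`
comments, Broad-dialect GMT for gene sets, SIF for networks.

## Prioritization rubric

`S = direct + transcriptional + min(overlap_count, 3)`, each flag in
{0, 1}. The overlap cap of 3 is kept even though four annotation sets
exist, because the stated rubric enumerates only 1–3 points; the cap is a
parameter (`overlap_cap`) for users whose rubric differs. Raw membership
counts are computed uncapped in the overlap layer and capped only here —
data and policy stay separate.

Ranking uses total score descending, then direct flag, then transcriptional
flag, then symbol — the tie-break beyond the total is this package's choice
(the source ranking is unspecified) and exists purely to make output a
deterministic total order.

Panel selection is configuration: a score threshold (default 3), explicit
manual includes/excludes, and an anchor gene (default the inhibited target).
The reference panel requires excluding CCL14 manually; published panels mix
rubric output with editorial judgement, so the package models that judgement
as explicit, auditable config rather than code.

## Overlap analysis

Venn decomposition assigns each gene of the union its exact membership
signature; regions therefore partition the union by construction, and the
implementation is checked against a per-gene brute-force oracle. Output is
sparse (a five-set diagram has 31 candidate regions, mostly empty); a flag
emits all of them. No graphical rendering is attempted.

## Enrichment

Right-tailed hypergeometric tail probabilities are computed with scipy's
log-space survival function and verified against closed-form enumeration
for every configuration with N ≤ 12. FDR is Benjamini–Hochberg step-up —
the reference analysis reports "FDR" without naming a procedure, so the
standard default is adopted openly. Zero-overlap pathways are tested
(p = 1) and count toward the BH denominator but are omitted from the
default report; this makes multiplicity accounting deterministic under
input reordering.

The universe defaults to the union of pathway members when not supplied.
The reference knowledge base's pathway definitions and universe are
proprietary, so the packaged pathway collection is a toy stand-in built
from the published per-pathway gene lists plus filler members; FDR values
computed over it are illustrative only and are deliberately not treated as
reproduction targets. One synthetic chemokine pathway supplements the ten
published ones so that every panel gene maps to at least one pathway, as
the source analysis states.

## Expression arithmetic

ΔCt = Ct_gene − Ct_HK per sample; basal abundance 2^−ΔCt; fold change
2^−ΔΔCt; percent change (FC − 1) × 100 rounded to the nearest integer;
direction flips exactly at FC = 1 (a fold change of exactly 1 is "nc").
Replicates are aggregated by mean Ct within (gene, group) before ΔΔCt; the
per-replicate-FC-then-geometric-mean alternative is algebraically identical
for balanced paired designs, which is why mean-Ct is the default and the
option collapses onto it.

Printed percent/direction cells, when present in an input table, are
validated against the rule above. Inconsistent cells (the reference table
contains exactly one, C7/ADAM9) are surfaced as warnings and never
corrected: the input stays authoritative, the audit trail records the
disagreement.

Viability is 100 × OD_treated / OD_untreated; assay summaries report the
arithmetic mean at one decimal plus min/max, matching how such panels are
quoted.

## Upstream-regulator inference

The activation z-score is the unweighted form z = Σ eᵢoᵢ / √N over targets
with known expected sign and non-flat observed direction. No edge weights
and no bias correction are applied: the weighted/bias-corrected variants of
the commercial implementation are unpublished, and the unweighted form
reproduces every reference value exactly, so anything further would be
speculation. Direction alone carries the evidence — no fold-change or
p-value cutoff gates the input, per the reference analysis protocol.

State calls use z > +2 (activated) and z < −2 (inhibited), both
configurable. Note that with N = 4 usable targets the statistic's range is
{−2,…,+2}: the extreme ±2 values are attainable but not exceedable, so the
null probability of reaching the boundary, 2·(1/2)⁴ = 0.125, is the
relevant calibration quantity at that size, and the strict >2 threshold can
never fire. This is a property of the statistic, not a defect of the
implementation.

Support and ranking come from the right-tail hypergeometric overlap p-value
(targets vs changed genes in the analysis universe), with ties broken by
|z| then label. A regulator whose own transcript is suppressed can still be
called activated — the score reflects its downstream network, and such
paradoxical calls are reported as-is.

The packaged causal network derives expected edge signs from the reference
tables: rows where |z| = √N or z = 0 force the consistency split exactly;
for the remainder the split size is implied by z and the assignment of
inconsistent edges to specific targets (which does not affect z) follows a
documented alphabetical convention. The one regulator printed with two z
values across compound subsets (TXN) is explained exactly by APOA1's
compound-specific direction, which independently pins that edge's sign.

## Synthetic data

Generators are pure functions of (spec, seed) and emit machine-readable
truth ledgers; recovery tests consume the ledger only.

*Gene sets* use partition-first allocation: each gene is assigned a Venn
signature, then sets are collected, so planted overlaps are exact by
construction; infeasible designs fail naming the violated set.

*Causal networks* give each regulator disjoint targets with random expected
signs; observed directions agree with the planted state with a configurable
consistency probability (fair coins for null regulators).

*Ct matrices* model noise as Gaussian on the cycle-threshold scale
(multiplicative on expression), sd 0.2 cycles per well by default — a
standard qPCR error magnitude. Noise applies to target-gene rows; the
housekeeping row is the deterministic reference, i.e. reference
variability is folded into the per-gene noise term rather than simulated
separately. The default replicate structure is three independent
experiments × two technical duplicates (six wells per gene and group),
mirroring the reference study's stated design. Under these defaults the
ΔΔCt estimator has sd 0.2·√(2/6) ≈ 0.115 cycles, so a planted 4-fold
knockdown is recovered within 20% in ≈98% of runs — the property the
recovery tests check at 500 seeds.

What the generators do *not* emulate: amplification-efficiency differences
between primers (no Pfaffl correction), inter-plate batch effects,
heteroscedastic noise at high Ct, and the scale or topology of a real
curated knowledge graph. Passing recovery tests therefore demonstrates the
arithmetic and inference are correct under the stated error model, not that
the pipeline is robust to every real-world artifact.

## Pipeline and determinism

Stages run in the fixed order prioritize → enrich → expression →
regulators → signature. Every filter logs in/out counts. Stage failures
abort with a stage-named error; validation warnings never abort. The report
body contains no timestamps and is byte-identical across reruns of the same
config; provenance records the package version, seed, and a SHA-256 over
the analytic config (the output directory is excluded — where results land
is not part of the analysis).

Signature concordance compares observed directions to a per-gene
expectation map that admits four values: Up, Dn, `variable`
(compound-specific, never scored as match/mismatch) and `adaptive` (the
escape axis; observed upregulation raises an adaptive flag rather than a
mismatch). `on_target` means the anchor gene is observed Dn.

## Problem sizes used in the checks

The verification suite runs at deliberately small scale, chosen to make
every oracle exhaustive or near-exhaustive: hypergeometric enumeration to
N = 12, Venn brute force on 100 random 4-set instances over 50 genes,
10,000-replicate null calibration of the z boundary event, 500-seed
fold-change recovery, and a 2,000-replicate enrichment null at
N = 20,000 / K = 2,000 / n = 1,000 where the discrete rejection rate
(≈0.049) is close enough to the nominal 0.05 for a meaningful calibration
check.

## Known limitations

- The curated downstream inventory ships only the 40 published interaction
  rows plus the 11 additional genes recoverable from the priority table;
  the full 113-gene inventory is not public, so the fixture universe is a
  52-gene subset of the real one.
- Enrichment FDRs depend on the (proprietary) pathway definitions and
  universe; only the structure of the analysis, not the printed FDR values,
  is reproducible.
- Regulator inference is depth-1: no mechanistic multi-step causal
  reasoning, no molecule-type ontology beyond free-text category tags.
- The expected-sign derivation for non-forced causal edges is
  z-equivalent but not unique at the per-edge level.
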