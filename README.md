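# netprior

Network-guided characterization of single-target inhibition, built around the
MMP12 (macrophage metalloelastase) suppression workflow in non-small cell
lung cancer (NSCLC): prioritize the target's curated downstream genes,
analyse their overlap with cancer-process gene sets and canonical pathways,
quantify treatment effects with qPCR ΔΔCt arithmetic, and infer causal
upstream regulators from the observed expression directions — assembled into
an eight-gene pharmacodynamic (PD) signature report.

It is written for computational biologists who have curated interaction
exports (e.g. from a commercial knowledge base) and qPCR readouts, and who
want the full triage-to-signature analysis to be scripted, testable and
auditable rather than run through a GUI.

## The statistics at the core

**Prioritization rubric (0–5).** Each downstream gene g of the inhibited
target scores

    S(g) = 1[direct interaction] + 1[transcriptional regulation] + min(k_g, 3)

where k_g is the number of cancer-associated annotation sets containing g.
Genes with S ≥ 3, minus explicit manual exclusions, plus the inhibited target
itself as anchor, form the validation panel.

**Over-representation.** A query of n genes against a pathway of K genes in a
universe of N genes, overlapping in k, is scored with the right-tailed
hypergeometric probability P[X ≥ k], X ~ Hypergeom(N, K, n) (the one-sided
Fisher exact test), with Benjamini–Hochberg step-up FDR across all tested
pathways.

**ΔΔCt arithmetic.** With Ct values normalized to a housekeeping gene,
ΔCt = Ct_gene − Ct_HK, basal abundance = 2^−ΔCt, and the treated-vs-control
fold change is FC = 2^−ΔΔCt; percent change is (FC − 1) × 100 with direction
Up/Dn/nc flipping exactly at FC = 1.

**Activation z-score.** For a regulator with signed target edges e_i and
observed directions o_i ∈ {+1, −1}, each usable target contributes
s_i = e_i·o_i and

    z = Σ s_i / √N,   |z| ≤ √N,

with z > +2 called activated and z < −2 inhibited. Support is the right-tail
hypergeometric overlap p-value between the regulator's targets and the
changed-gene list; calls are ranked by that p-value. Note the score reads
downstream network behaviour, not the regulator's own transcript — a
pharmacologically inhibited target can legitimately receive a positive z.

## Worked example

The package ships the transcribed reference dataset (40 curated downstream
interactions, the 21-row priority table inputs, the 40-row fold-change table
for five inhibitors C1/C7/C9/C10/C15, and a derived signed causal network):

```bash
netprior run --fixtures --outdir out/
```

prints

```
panel (8): ADAM9, APOA1, CCL15, CD44, MMP12, NFKBIA, PSME3, SPARCL1
on-target in all compounds: True
report: out/report.json
```

The panel is the eight-gene PD signature: NFKBIA and CD44 score 4, six genes
score 3 (CCL14 is manually excluded, configured — not hard-coded), and MMP12
enters as the anchor. `on-target` means the anchor is called Dn (fold change
< 1) under every compound. The run emits exactly one data-consistency
warning — the C7/ADAM9 percent cell, whose printed value disagrees with the
(FC−1)×100 rule — which is flagged, never silently corrected. Per-compound
regulator calls land in `out/regulator_calls_C*.tsv`; for example C9 contains
`CRK/CRKL ... -2.24 ... inhibited`, an inhibited-state call from five fully
inconsistent targets (z = −5/√5).

The same stages are available individually (`netprior prioritize`,
`enrich`, `expression`, `regulators`, `simulate`) and as library functions
(`netprior.build_priority_table`, `netprior.activation_zscore`, ...).

## Layout

- `netprior.core` / `netprior.io` — domain types, symbol normalization, TSV/GMT/SIF readers and writers
- `netprior.overlap` — Venn region decomposition and membership counts
- `netprior.prioritize` — the 0–5 rubric, ranking, panel selection
- `netprior.enrich` — hypergeometric ORA, BH-FDR, pathway connectivity graph
- `netprior.expression` — ΔCt/ΔΔCt arithmetic, direction calls, assay summaries
- `netprior.regulators` — activation z-scores, overlap p-values, consensus, biomarker annotation, network export
- `netprior.synthetic` — seeded generators with planted ground truth
- `netprior.pipeline` / `netprior.cli` — orchestration, config, report, CLI
- `netprior.datasets` — packaged transcribed fixtures and synthetic stand-ins

See `docs/methods.md` for the modelling assumptions and design choices.
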