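"""End-to-end orchestration: prioritize -> enrich -> expression -> regulators
-> signature, with structured per-stage logging and a deterministic report.

The pipeline consumes the six input files (interaction table, direct-target
list, annotation GMT, pathway GMT, expression input, causal edge list, plus
optional biomarker catalog and expected-direction map), applies each stage's
documented filters, and assembles a run report whose body is a pure function
of config + inputs: identical config and seed reproduce an identical report
byte for byte.  Validation warnings (e.g. a printed percent cell that
disagrees with its fold change) are collected, logged and reported; they
never abort a run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from . import __version__
from . import io as npio
from .core import GeneSet, GeneSetCollection, NetpriorError
from .enrich import (
    enrich_gene_list,
    pathway_connectivity,
    write_enrichment_table,
    write_pathway_graph,
)
from .expression import (
    ExpressionChange,
    ct_matrix_fold_changes,
    validate_printed_percent,
    write_expression_table,
)
from .prioritize import (
    PanelSelection,
    build_priority_table,
    select_panel,
    write_priority_table,
)
from .regulators import (
    call_regulators,
    consensus_regulators,
    annotate_biomarkers,
    export_signature_network,
    write_regulator_calls,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "signature_concordance", "StageError"]


class StageError(NetpriorError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All inputs and parameters of one pipeline run."""

    # input files
    interactions: Path
    direct_targets: Path
    annotation_sets: Path
    pathways: Path
    expression_table: Optional[Path]
    causal_network: Path
    universe: Path
    supplement: Optional[Path] = None
    biomarker_catalog: Optional[Path] = None
    expected_directions: Optional[Path] = None
    ct_matrix: Optional[Path] = None
    ct_samples: Optional[Path] = None
    # rubric parameters
    threshold: int = 3
    overlap_cap: int = 3
    manual_excludes: tuple = ()
    manual_includes: tuple = ()
    anchor: str = "MMP12"
    # enrichment parameters
    enrichment_universe: str = "pathway_union"  # or "file"
    # regulator parameters
    p_max: float = 0.05
    z_hi: float = 2.0
    z_lo: float = -2.0
    category_filter: Optional[tuple] = None
    # expression parameters
    aggregation: str = "mean_ct"
    housekeeping: str = "GAPDH"
    control_group: str = "untreated"
    # run parameters
    outdir: Path = Path("netprior_out")
    seed: int = 0

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        base = Path(path).parent
        inputs = raw.get("inputs", {})

        def p(key):
            return (base / inputs[key]).resolve() if key in inputs else None

        kwargs = dict(
            interactions=p("interactions"),
            direct_targets=p("direct_targets"),
            annotation_sets=p("annotation_sets"),
            pathways=p("pathways"),
            expression_table=p("expression_table"),
            causal_network=p("causal_network"),
            universe=p("universe"),
            supplement=p("supplement"),
            biomarker_catalog=p("biomarker_catalog"),
            expected_directions=p("expected_directions"),
            ct_matrix=p("ct_matrix"),
            ct_samples=p("ct_samples"),
        )
        rubric = raw.get("rubric", {})
        for key in ("threshold", "overlap_cap", "anchor"):
            if key in rubric:
                kwargs[key] = rubric[key]
        kwargs["manual_excludes"] = tuple(rubric.get("manual_excludes", ()))
        kwargs["manual_includes"] = tuple(rubric.get("manual_includes", ()))
        regulators = raw.get("regulators", {})
        for key in ("p_max", "z_hi", "z_lo"):
            if key in regulators:
                kwargs[key] = regulators[key]
        if "category_filter" in regulators:
            kwargs["category_filter"] = tuple(regulators["category_filter"])
        expr = raw.get("expression", {})
        for key in ("aggregation", "housekeeping", "control_group"):
            if key in expr:
                kwargs[key] = expr[key]
        enrichment = raw.get("enrichment", {})
        if "universe" in enrichment:
            kwargs["enrichment_universe"] = enrichment["universe"]
        run = raw.get("run", {})
        if "outdir" in run:
            kwargs["outdir"] = (base / run["outdir"]).resolve()
        if "seed" in run:
            kwargs["seed"] = int(run["seed"])
        return cls(**kwargs)

    @classmethod
    def fixture_config(cls, outdir) -> "PipelineConfig":
        """Configuration pointing at the packaged reference fixtures."""
        from . import datasets

        return cls(
            interactions=datasets.data_path("downstream_interactions.tsv"),
            supplement=datasets.data_path("downstream_supplement.tsv"),
            direct_targets=datasets.data_path("direct_targets.txt"),
            annotation_sets=datasets.data_path("annotation_sets.gmt"),
            pathways=datasets.data_path("pathways.gmt"),
            expression_table=datasets.data_path("expression_changes.tsv"),
            causal_network=datasets.data_path("causal_network.tsv"),
            universe=datasets.data_path("universe.txt"),
            biomarker_catalog=datasets.data_path("biomarker_catalog.tsv"),
            expected_directions=datasets.data_path("expected_directions.tsv"),
            manual_excludes=("CCL14",),
            anchor="MMP12",
            outdir=Path(outdir),
        )

    def config_hash(self) -> str:
        # the output location is not an analytic parameter: two runs of the
        # same inputs into different directories are the same analysis
        payload = {k: str(v) for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode("utf-8")
        ).hexdigest()


@dataclass
class RunReport:
    """All pipeline outputs plus provenance, serializable as JSON."""

    priority: List[dict]
    panel: List[str]
    enrichment: List[dict]
    pathway_edges: List[dict]
    expression: List[dict]
    validation_warnings: List[dict]
    regulator_calls: Dict[str, List[dict]]
    consensus: List[dict]
    signature: dict
    biomarkers: Optional[dict]
    provenance: dict

    def body_json(self) -> str:
        """Deterministic report body (no timestamps)."""
        return json.dumps(asdict(self), sort_keys=True, indent=1)


def _read_expression(config: PipelineConfig):
    """Expression changes from either a fold-change table or a Ct matrix."""
    if config.expression_table is not None:
        changes: List[ExpressionChange] = []
        printed: Dict[tuple, tuple] = {}
        with open(config.expression_table, encoding="utf-8") as fh:
            lines = [
                l.rstrip("\n")
                for l in fh
                if l.strip() and not l.lstrip().startswith("#")
            ]
        header = [h.strip().lower().rstrip("*").strip() for h in lines[0].split("\t")]
        cols = {name: i for i, name in enumerate(header)}
        for required in ("compound", "gene", "fold change"):
            if required not in cols:
                raise npio.SchemaError(
                    f"{config.expression_table}: missing required column {required!r}"
                )
        for line in lines[1:]:
            fields = line.split("\t")
            change = ExpressionChange.from_fold_change(
                fields[cols["gene"]],
                fields[cols["compound"]],
                float(fields[cols["fold change"]]),
            )
            changes.append(change)
            if "% change" in cols:
                printed[(change.compound, change.gene)] = (
                    fields[cols["% change"]],
                    fields[cols["direction"]] if "direction" in cols else "",
                )
        issues = validate_printed_percent(changes, printed) if printed else []
        return changes, issues
    if config.ct_matrix is None or config.ct_samples is None:
        raise StageError("expression: need either expression_table or ct_matrix + ct_samples")
    ctm = npio.read_ct_matrix(config.ct_matrix, config.ct_samples, config.housekeeping)
    return ct_matrix_fold_changes(ctm, config.control_group, config.aggregation), []


def signature_concordance(
    panel: Sequence[str],
    expected: Dict[str, str],
    changes: Sequence[ExpressionChange],
    anchor: str = "MMP12",
) -> dict:
    """Per-compound concordance of the panel with its expected directions.

    For each compound: per-gene observed/expected/match entries (match only
    defined for a fixed Up/Dn expectation), an ``on_target`` flag (anchor
    observed Dn), and an ``adaptive`` list -- genes observed Up whose
    therapeutic expectation is not Up (down-expected, variable, or the
    designated adaptive axis).  Panel genes missing from a compound's
    changes are listed as unevaluated with a logged warning.
    """
    by_compound: Dict[str, Dict[str, ExpressionChange]] = {}
    for change in changes:
        by_compound.setdefault(change.compound, {})[change.gene] = change
    report: dict = {"anchor": anchor, "compounds": {}}
    for compound in sorted(by_compound):
        observed = by_compound[compound]
        genes_entry = {}
        unevaluated = []
        adaptive = []
        n_matches = 0
        for gene in sorted(panel):
            exp = expected.get(gene)
            change = observed.get(gene)
            if change is None:
                unevaluated.append(gene)
                logger.warning("signature: %s missing from %s changes", gene, compound)
                genes_entry[gene] = {"observed": None, "expected": exp, "match": None}
                continue
            obs = change.direction.value
            match = obs == exp if exp in ("Up", "Dn") else None
            if match:
                n_matches += 1
            if obs == "Up" and exp in ("Dn", "variable", "adaptive"):
                adaptive.append(gene)
            genes_entry[gene] = {"observed": obs, "expected": exp, "match": match}
        anchor_change = observed.get(anchor)
        report["compounds"][compound] = {
            "genes": genes_entry,
            "on_target": bool(anchor_change and anchor_change.direction.value == "Dn"),
            "adaptive": adaptive,
            "unevaluated": unevaluated,
            "n_matches": n_matches,
        }
    report["on_target_all"] = all(
        entry["on_target"] for entry in report["compounds"].values()
    )
    return report


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in order and write every artifact to the outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # -- prioritize ---------------------------------------------------------
    try:
        records = npio.read_interaction_table(config.interactions)
        if config.supplement is not None:
            records += npio.read_interaction_table(config.supplement)
        direct = GeneSet(
            name="direct",
            category="direct",
            members=frozenset(npio.read_symbol_list(config.direct_targets)),
        )
        annotation = npio.read_gmt(config.annotation_sets)
        priority = build_priority_table(
            records, direct, list(annotation), overlap_cap=config.overlap_cap
        )
        selection = PanelSelection(
            threshold=config.threshold,
            manual_excludes=config.manual_excludes,
            manual_includes=config.manual_includes,
            anchor=config.anchor,
        )
        panel = select_panel(priority, selection)
    except (OSError, NetpriorError, ValueError) as exc:
        raise StageError(f"prioritize: {exc}") from exc
    logger.info(
        "prioritize: %d interaction records -> %d scored genes -> %d panel genes "
        "(threshold %d, excludes %s)",
        len(records),
        len(priority),
        len(panel),
        config.threshold,
        list(config.manual_excludes),
    )
    write_priority_table(priority, outdir / "priority_table.tsv")
    panel_set = GeneSet(name="panel", category="panel", members=panel)
    npio.write_gmt(GeneSetCollection(sets=(panel_set,)), outdir / "panel.gmt")

    # -- enrich -------------------------------------------------------------
    try:
        pathways = npio.read_gmt(config.pathways)
        universe_file = frozenset(npio.read_symbol_list(config.universe))
        enrich_universe = (
            None if config.enrichment_universe == "pathway_union" else universe_file
        )
        results = enrich_gene_list(panel_set, pathways, universe=enrich_universe)
        graph = pathway_connectivity(results)
    except (OSError, NetpriorError, ValueError) as exc:
        raise StageError(f"enrich: {exc}") from exc
    logger.info(
        "enrich: %d/%d pathways overlap the %d-gene panel",
        len(results),
        len(pathways),
        len(panel),
    )
    write_enrichment_table(results, outdir / "enrichment.tsv")
    write_pathway_graph(graph, outdir / "pathway_graph.sif", outdir / "pathway_graph_edges.tsv")

    # -- expression ---------------------------------------------------------
    try:
        changes, issues = _read_expression(config)
    except (OSError, NetpriorError, ValueError) as exc:
        raise StageError(f"expression: {exc}") from exc
    for issue in issues:
        logger.warning(
            "expression validation: %s/%s: %s", issue.compound, issue.gene, issue.message
        )
    logger.info("expression: %d change records, %d validation warning(s)", len(changes), len(issues))
    write_expression_table(changes, outdir / "expression_changes.tsv")

    # -- regulators ---------------------------------------------------------
    try:
        network = npio.read_causal_edges(config.causal_network)
        category_filter = set(config.category_filter) if config.category_filter else None
        compounds = sorted({c.compound for c in changes})
        calls_by_compound = {}
        for compound in compounds:
            subset = [c for c in changes if c.compound == compound]
            calls_by_compound[compound] = call_regulators(
                network,
                subset,
                set(universe_file),
                p_max=config.p_max,
                z_hi=config.z_hi,
                z_lo=config.z_lo,
                category_filter=category_filter,
            )
        consensus = consensus_regulators(calls_by_compound)
    except (OSError, NetpriorError, ValueError) as exc:
        raise StageError(f"regulators: {exc}") from exc
    for compound, calls in calls_by_compound.items():
        logger.info(
            "regulators: %s: %d call(s) at p < %g", compound, len(calls), config.p_max
        )
        write_regulator_calls(calls, outdir / f"regulator_calls_{compound}.tsv")
    export_signature_network(
        network,
        changes,
        outdir / "signature_network.sif",
        outdir / "signature_network_nodes.tsv",
        outdir / "signature_network_edges.tsv",
    )

    # -- signature ----------------------------------------------------------
    expected = {}
    if config.expected_directions is not None:
        with open(config.expected_directions, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "gene\t")):
                    continue
                gene, exp = line.rstrip("\n").split("\t")
                expected[gene] = exp
    signature = signature_concordance(sorted(panel), expected, changes, anchor=config.anchor)

    biomarkers = None
    if config.biomarker_catalog is not None:
        try:
            biomarkers = annotate_biomarkers(panel_set, config.biomarker_catalog)
        except (OSError, NetpriorError, ValueError) as exc:
            raise StageError(f"biomarkers: {exc}") from exc
        logger.info(
            "biomarkers: %d/%d panel genes annotated",
            sum(v is not None for v in biomarkers.values()),
            len(biomarkers),
        )

    report = RunReport(
        priority=[asdict(r) for r in priority],
        panel=sorted(panel),
        enrichment=[
            {
                "pathway": r.pathway,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p": r.p,
                "fdr": r.fdr,
                "genes": sorted(r.overlap_genes),
            }
            for r in results
        ],
        pathway_edges=[
            {"a": a, "b": b, "weight": d["weight"], "shared": d["shared"]}
            for a, b, d in sorted(graph.edges(data=True))
        ],
        expression=[
            {
                "compound": c.compound,
                "gene": c.gene,
                "fold_change": c.fold_change,
                "percent_change": c.percent_change,
                "direction": c.direction.value,
            }
            for c in changes
        ],
        validation_warnings=[asdict(i) for i in issues],
        regulator_calls={
            compound: [
                {
                    "regulator": c.regulator,
                    "category": c.category,
                    "n_used": c.n_used,
                    "n_consistent": c.n_consistent,
                    "n_inconsistent": c.n_inconsistent,
                    "z": round(c.z, 6),
                    "p_overlap": c.p_overlap,
                    "state": c.state.value,
                }
                for c in calls
            ]
            for compound, calls in calls_by_compound.items()
        },
        consensus=consensus,
        signature=signature,
        biomarkers=biomarkers,
        provenance={
            "package": "netprior",
            "version": __version__,
            "config_sha256": config.config_hash(),
            "seed": config.seed,
        },
    )
    (outdir / "report.json").write_text(report.body_json(), encoding="utf-8")
    return report
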