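"""Readers and writers for the package's plain-text interchange formats.

All tabular files are UTF-8, tab-separated, with ``#`` comment lines ignored
(matching GMT conventions).  Gene sets use the standard Broad GMT dialect:
``name<TAB>description<TAB>member...``.  Network exports use SIF
(``source<TAB>relation<TAB>target``).
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

from .core import (
    CausalEdge,
    CtMatrix,
    Effect,
    GeneSet,
    GeneSetCollection,
    InteractionRecord,
    Mechanism,
    ODPlate,
    ParseError,
    Sample,
    SchemaError,
    normalize_symbol,
)

logger = logging.getLogger(__name__)

_INTERACTION_COLUMNS = {
    "downstream network object": "object_name",
    "genesymbol": "target",
    "effect": "effect",
    "mechanism": "mechanism",
}


def _data_lines(path) -> Iterable[Tuple[int, list]]:
    """Yield (1-based line number, fields) for non-comment, non-blank lines."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def _canon_header(field: str) -> str:
    return field.strip().lstrip("﻿").rstrip("*").strip().lower()


def read_interaction_table(path, source: str = "MMP12") -> list:
    """Read a curated interaction table (one row per downstream edge).

    The header must contain (order- and case-insensitively) the columns
    ``Downstream Network Object``, ``GeneSymbol``, ``Effect``, ``Mechanism``.
    Duplicate (source, target, mechanism) rows collapse to one with a logged
    warning; curated exports commonly repeat edges.
    """
    rows = list(_data_lines(path))
    if not rows:
        raise SchemaError(f"{path}: empty interaction table (no header)")
    _, header = rows[0]
    index = {}
    for i, field in enumerate(header):
        key = _canon_header(field)
        if key in _INTERACTION_COLUMNS:
            index[_INTERACTION_COLUMNS[key]] = i
    for key, col in _INTERACTION_COLUMNS.items():
        if col not in index:
            raise SchemaError(f"{path}: missing required column {key!r}")

    records: list = []
    seen: set = set()
    n_dupes = 0
    for lineno, fields in rows[1:]:
        if len(fields) <= max(index.values()):
            raise ParseError(f"{path}:{lineno}: expected {len(index)} columns, got {len(fields)}")
        try:
            rec = InteractionRecord(
                source=source,
                object_name=fields[index["object_name"]].strip().strip("*"),
                target=fields[index["target"]].strip().strip("*"),
                effect=Effect.parse(fields[index["effect"]]),
                mechanism=Mechanism.parse(fields[index["mechanism"]]),
            )
        except ParseError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        key = (rec.source, rec.target, rec.mechanism)
        if key in seen:
            n_dupes += 1
            continue
        seen.add(key)
        records.append(rec)
    if n_dupes:
        logger.warning("%s: collapsed %d duplicate interaction row(s)", path, n_dupes)
    return records


def write_interaction_table(records: Sequence[InteractionRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("Downstream Network Object\tGeneSymbol\tEffect\tMechanism\n")
        for rec in records:
            fh.write(
                f"{rec.object_name}\t{rec.target}\t"
                f"{rec.effect.value}\t{rec.mechanism.value}\n"
            )


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file.

    Field 2 (the GMT "description") is stored as the set's category tag.
    Duplicate members within a line are collapsed; duplicate set names are an
    error.
    """
    sets: list = []
    names: set = set()
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
        name = fields[0].strip()
        if name in names:
            raise ParseError(f"{path}:{lineno}: duplicate gene set name {name!r}")
        names.add(name)
        members = frozenset(normalize_symbol(m) for m in fields[2:] if m.strip())
        sets.append(GeneSet(name=name, category=fields[1].strip(), members=members))
    return GeneSetCollection(sets=tuple(sets))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.category, *sorted(s.members)]) + "\n")


def read_symbol_list(path) -> list:
    """Read one gene symbol per line (comments/blank lines ignored)."""
    return [normalize_symbol(fields[0]) for _, fields in _data_lines(path)]


def write_symbol_list(symbols: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for sym in symbols:
            fh.write(normalize_symbol(sym) + "\n")


def read_causal_edges(path) -> list:
    """Read a signed regulator->target edge list.

    Columns: ``regulator``, ``target``, ``expected_sign`` and optionally
    ``category``.  Duplicate (regulator, target) pairs are an error.
    """
    rows = list(_data_lines(path))
    if not rows:
        raise SchemaError(f"{path}: empty causal edge table")
    _, header = rows[0]
    cols = {_canon_header(f): i for i, f in enumerate(header)}
    for required in ("regulator", "target", "expected_sign"):
        if required not in cols:
            raise SchemaError(f"{path}: missing required column {required!r}")
    edges: list = []
    seen: set = set()
    for lineno, fields in rows[1:]:
        try:
            sign = int(fields[cols["expected_sign"]])
        except (ValueError, IndexError):
            raise ParseError(f"{path}:{lineno}: expected_sign must be an integer") from None
        category = fields[cols["category"]].strip() if "category" in cols else ""
        try:
            edge = CausalEdge(
                regulator=fields[cols["regulator"]],
                target=fields[cols["target"]],
                expected_sign=sign,
                category=category,
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        key = (edge.regulator, edge.target)
        if key in seen:
            raise ParseError(f"{path}:{lineno}: duplicate edge {key}")
        seen.add(key)
        edges.append(edge)
    return edges


def write_causal_edges(edges: Sequence[CausalEdge], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("regulator\ttarget\texpected_sign\tcategory\n")
        for e in edges:
            fh.write(f"{e.regulator}\t{e.target}\t{e.expected_sign:+d}\t{e.category}\n")


def read_ct_matrix(matrix_path, samples_path, housekeeping: str) -> CtMatrix:
    """Read a wide Ct matrix plus its sample side-table.

    ``matrix_path``: first column ``gene``, remaining columns one per sample id;
    empty cells or ``NA`` mark missing values.  ``samples_path``: columns
    ``sample_id``, ``group``, optional ``compound``.
    """
    sample_rows = list(_data_lines(samples_path))
    if not sample_rows:
        raise SchemaError(f"{samples_path}: empty sample table")
    _, sheader = sample_rows[0]
    scols = {_canon_header(f): i for i, f in enumerate(sheader)}
    for required in ("sample_id", "group"):
        if required not in scols:
            raise SchemaError(f"{samples_path}: missing required column {required!r}")
    samples_by_id = {}
    for lineno, fields in sample_rows[1:]:
        compound = fields[scols["compound"]].strip() if "compound" in scols else ""
        sample = Sample(
            sample_id=fields[scols["sample_id"]].strip(),
            group=fields[scols["group"]].strip(),
            compound=compound,
        )
        samples_by_id[sample.sample_id] = sample

    rows = list(_data_lines(matrix_path))
    if not rows:
        raise SchemaError(f"{matrix_path}: empty Ct matrix")
    _, header = rows[0]
    sample_ids = [f.strip() for f in header[1:]]
    missing = [sid for sid in sample_ids if sid not in samples_by_id]
    if missing:
        raise SchemaError(f"{matrix_path}: sample ids missing from side-table: {missing}")
    genes: list = []
    values: list = []
    for lineno, fields in rows[1:]:
        if len(fields) != len(sample_ids) + 1:
            raise ParseError(
                f"{matrix_path}:{lineno}: expected {len(sample_ids) + 1} fields, got {len(fields)}"
            )
        genes.append(fields[0])
        row = []
        for cell in fields[1:]:
            cell = cell.strip()
            if cell in ("", "NA", "NaN", "nan"):
                row.append(np.nan)
            else:
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ParseError(f"{matrix_path}:{lineno}: bad Ct value {cell!r}") from None
        values.append(row)
    return CtMatrix(
        genes=genes,
        samples=[samples_by_id[sid] for sid in sample_ids],
        ct=np.array(values, dtype=float),
        housekeeping=housekeeping,
    )


def write_ct_matrix(ctm: CtMatrix, matrix_path, samples_path) -> None:
    with open(matrix_path, "w", encoding="utf-8", newline="") as fh:
        fh.write("gene\t" + "\t".join(s.sample_id for s in ctm.samples) + "\n")
        for gene, row in zip(ctm.genes, ctm.ct):
            cells = ["" if np.isnan(v) else f"{v:.4f}" for v in row]
            fh.write(gene + "\t" + "\t".join(cells) + "\n")
    with open(samples_path, "w", encoding="utf-8", newline="") as fh:
        fh.write("sample_id\tgroup\tcompound\n")
        for s in ctm.samples:
            fh.write(f"{s.sample_id}\t{s.group}\t{s.compound}\n")


def read_od_plate(path, control_group: str = "untreated") -> ODPlate:
    """Read an optical-density plate table with columns ``group``, ``value``."""
    rows = list(_data_lines(path))
    if not rows:
        raise SchemaError(f"{path}: empty OD plate table")
    _, header = rows[0]
    cols = {_canon_header(f): i for i, f in enumerate(header)}
    for required in ("group", "value"):
        if required not in cols:
            raise SchemaError(f"{path}: missing required column {required!r}")
    readings: dict = {}
    for lineno, fields in rows[1:]:
        try:
            value = float(fields[cols["value"]])
        except (ValueError, IndexError):
            raise ParseError(f"{path}:{lineno}: bad optical density") from None
        readings.setdefault(fields[cols["group"]].strip(), []).append(value)
    return ODPlate(readings=readings, control_group=control_group)


def write_sif(edges: Sequence[Tuple[str, str, str]], path) -> None:
    """Write (source, relation, target) triples as SIF, in given order."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for source, relation, target in edges:
            fh.write(f"{source}\t{relation}\t{target}\n")


def read_sif(path) -> list:
    edges = []
    for lineno, fields in _data_lines(path):
        if len(fields) != 3:
            raise ParseError(f"{path}:{lineno}: SIF line needs exactly 3 fields")
        edges.append((fields[0], fields[1], fields[2]))
    return edges
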