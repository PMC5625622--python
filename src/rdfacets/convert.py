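"""Tabular → RDF conversion.

A delimited table is viewed as a collection of row objects: row *i* becomes
the subject ``<namespace>i``, column *j* becomes the predicate
``<namespace>P_j``, and each non-empty cell (i, j) becomes one
(subject, predicate, literal) statement. Literals carry the column's
declared datatype; values of dependent columns are stored with their
prerequisite value prepended as ``prerequisite:value`` (e.g. a genomic
coordinate stored as ``chr5:1234``), which makes the facet value
self-describing and facet counting a plain group-by.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field

from rdflib import Graph, Literal, URIRef

from .errors import ConversionError
from .schema import ColumnSpec, DatabaseSpec, DatabaseStructure, canonical_ntriples

_INTEGER_RE = re.compile(r"^[+-]?\d+$")
_DECIMAL_RE = re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)$")


@dataclass
class TableSource:
    """An in-memory delimited table: one row per record, one column per facet."""

    database_name: str
    header: list[str]
    rows: list[dict[str, str]]

    def __post_init__(self):
        if len(set(self.header)) != len(self.header):
            raise ConversionError(
                f"table for {self.database_name!r}: duplicate header names")
        for i, row in enumerate(self.rows):
            missing = set(self.header) - set(row)
            if missing:
                raise ConversionError(
                    f"table for {self.database_name!r}, row {i + 1}: missing "
                    f"cells for {sorted(missing)}")


def read_table(text: str, database_name: str, delimiter: str = "\t") -> TableSource:
    """Parse CSV/TSV text (RFC-4180-style quoting) into a :class:`TableSource`."""
    reader = csv.reader(io.StringIO(text), delimiter=delimiter)
    rows = list(reader)
    if not rows:
        return TableSource(database_name, [], [])
    header = rows[0]
    records = []
    for r in rows[1:]:
        r = r + [""] * (len(header) - len(r))
        records.append(dict(zip(header, r)))
    return TableSource(database_name, header, records)


@dataclass
class SkippedCell:
    row_index: int
    column: str
    value: str
    reason: str


@dataclass
class ConversionReport:
    """Per-column triple counts and per-cell diagnostics for one table."""

    database_name: str
    n_rows: int = 0
    triples: int = 0
    triples_per_column: dict[str, int] = field(default_factory=dict)
    skipped: list[SkippedCell] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "database": self.database_name,
            "rows": self.n_rows,
            "triples": self.triples,
            "triples_per_column": dict(self.triples_per_column),
            "skipped_cells": [vars(s) for s in self.skipped],
            "warnings": list(self.warnings),
        }


def row_subject_iri(namespace: str, row_index: int) -> URIRef:
    """Subject IRI of the *row_index*-th row (1-based) under *namespace*."""
    if row_index < 1:
        raise ValueError(f"row_index must be >= 1, got {row_index}")
    return URIRef(namespace + str(row_index))


def column_predicate_iri(namespace: str, spec: ColumnSpec) -> URIRef:
    """Predicate IRI of a column under its database namespace."""
    return URIRef(namespace + spec.predicate_local_name)


def apply_dependency_prefix(value: str, dependent_value: str) -> str:
    """Prefix a facet value with its prerequisite, colon-separated.

    Splitting the stored form on the first colon recovers the prerequisite
    and the raw value; colons inside the prerequisite itself are not escaped.
    """
    if not value or not dependent_value:
        raise ValueError("both value and dependent_value must be non-empty")
    return f"{dependent_value}:{value}"


def _valid_for_datatype(value: str, datatype: str) -> bool:
    if datatype == "integer":
        return bool(_INTEGER_RE.match(value))
    if datatype == "decimal":
        return bool(_DECIMAL_RE.match(value))
    return True


def convert_table(table: TableSource, structure: DatabaseStructure
                  ) -> tuple[Graph, ConversionReport]:
    """Convert one table into data triples under its database's namespace.

    One triple per non-empty, datatype-valid cell; rows are numbered 1..n in
    file order. Datatype-invalid cells are recorded in the report and
    skipped; conversion continues. Dependent columns store the colon-prefixed
    form as a plain string literal (the prefixed lexical form is not a valid
    numeric literal even when the raw cell is).
    """
    try:
        db: DatabaseSpec = structure.database(table.database_name)
    except KeyError:
        raise ConversionError(
            f"database {table.database_name!r} is not declared in the structure")
    declared = {c.column_name for c in db.columns}
    undeclared = [h for h in table.header if h not in declared]
    if undeclared:
        raise ConversionError(
            f"database {db.name!r}: undeclared column(s) in header: {undeclared}")

    report = ConversionReport(database_name=db.name, n_rows=len(table.rows))
    for h in table.header:
        report.triples_per_column[h] = 0
    g = Graph()

    for i, row in enumerate(table.rows, start=1):
        subject = row_subject_iri(db.namespace, i)
        for h in table.header:
            raw = row[h]
            if raw == "":
                continue
            col = db.column(h)
            if not _valid_for_datatype(raw, col.datatype):
                report.skipped.append(SkippedCell(
                    i, h, raw, f"not a valid {col.datatype}"))
                continue
            chain = db.dependency_chain(h)
            if chain:
                prefixes = []
                for prereq in chain:
                    pv = row.get(prereq.column_name, "")
                    if pv == "":
                        report.warnings.append(
                            f"row {i}, column {h!r}: prerequisite "
                            f"{prereq.column_name!r} is empty; value emitted "
                            "without that prefix")
                    else:
                        prefixes.append(pv)
                lit = Literal(":".join(prefixes + [raw])) if prefixes else Literal(raw)
            else:
                lit = (Literal(raw) if col.xsd_datatype is None
                       else Literal(raw, datatype=col.xsd_datatype))
            g.add((subject, column_predicate_iri(db.namespace, col), lit))
            report.triples_per_column[h] += 1
    report.triples = len(g)
    return g, report


def strip_dependency_prefix(stored: str) -> tuple[str | None, str]:
    """Split a stored dependent-facet value into (prerequisite, raw value).

    Defined as a split on the first colon; returns ``(None, stored)`` when no
    colon is present.
    """
    if ":" in stored:
        prereq, raw = stored.split(":", 1)
        return prereq, raw
    return None, stored


def serialize_data(g: Graph, fmt: str = "nt") -> str:
    """Serialize data triples; ``nt`` output is canonical (sorted lines)."""
    if fmt == "nt":
        return canonical_ntriples(g)
    return g.serialize(format=fmt)
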