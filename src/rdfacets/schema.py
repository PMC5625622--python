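"""Database structure configuration and its RDFS description.

A collection of tabular databases is described to the search engine by a
structure configuration: which databases exist, how they nest, and — per
column — the predicate name, display label and order, whether the column is
hidden from facet generation, whether its literals are free-text indexed,
the literal datatype, an optional dependency on another column (a facet
whose values are meaningless without a prerequisite value, e.g. a genomic
coordinate without its chromosome), and an optional biological entity tag.

The configuration is a YAML document::

    collections:
      - name: NCBI
    databases:
      - name: dbSNP
        namespace: https://example.org/dbsnp/
        parent: NCBI
        columns:
          - column: SNP_Name
            display_name: Name of the SNP
            entity_type: snp

The structure is mirrored into RDF so a store is self-describing: each
database is an ``rdfs:Class`` typed ``rdx:Database``, nesting uses
``rdfs:subClassOf``, each column predicate is tied to its database with
``rdfs:domain``, a dependency between two column predicates is stated with
``rdfs:seeAlso`` (dependent → prerequisite), and the remaining per-column
attributes are statements about the predicate in a small project vocabulary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import yaml
from rdflib import BNode, Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import XSD

from .errors import ConfigParseError, StructureValidationError

#: Project vocabulary for per-column attribute statements.
VOCAB = Namespace("https://rdfacets.io/vocab#")
#: Namespace under which database/collection class IRIs are minted.
STRUCT = Namespace("https://rdfacets.io/structure/")

DATATYPES = ("string", "integer", "decimal")
ENTITY_TYPES = ("gene", "protein", "snp", "pathway", "publication", "none")

# IRI path-segment safe local names: unreserved characters only.
_LOCAL_NAME_RE = re.compile(r"^[A-Za-z0-9_.\-~]+$")

_XSD_FOR_DATATYPE = {
    "string": None,  # plain literal
    "integer": XSD.integer,
    "decimal": XSD.decimal,
}


@dataclass(frozen=True)
class ColumnSpec:
    """One table column / facet and its presentation & indexing attributes."""

    column_name: str
    predicate_local_name: str
    display_name: str
    display_order: int
    hidden: bool = False
    indexed: bool = True
    datatype: str = "string"
    depends_on: str | None = None
    entity_type: str | None = None

    def __post_init__(self):
        if not _LOCAL_NAME_RE.match(self.predicate_local_name):
            raise StructureValidationError(
                f"column {self.column_name!r}: predicate local name "
                f"{self.predicate_local_name!r} contains characters illegal "
                "in an IRI path segment")
        if self.display_order < 0:
            raise StructureValidationError(
                f"column {self.column_name!r}: display_order must be >= 0")
        if self.datatype not in DATATYPES:
            raise StructureValidationError(
                f"column {self.column_name!r}: unknown datatype "
                f"{self.datatype!r} (expected one of {DATATYPES})")
        if self.entity_type is not None and self.entity_type not in ENTITY_TYPES:
            raise StructureValidationError(
                f"column {self.column_name!r}: unknown entity_type "
                f"{self.entity_type!r}")

    @property
    def xsd_datatype(self):
        return _XSD_FOR_DATATYPE[self.datatype]


@dataclass(frozen=True)
class DatabaseSpec:
    """One converted tabular database: unique name, namespace, columns."""

    name: str
    namespace: str
    parent: str | None = None
    columns: tuple[ColumnSpec, ...] = ()

    def __post_init__(self):
        if not self.namespace or not self.namespace.endswith(("/", "#")):
            raise StructureValidationError(
                f"database {self.name!r}: namespace must be a base IRI "
                "ending in '/' or '#'")
        orders = [c.display_order for c in self.columns]
        if len(set(orders)) != len(orders):
            raise StructureValidationError(
                f"database {self.name!r}: display_order values must be "
                "unique within one database")
        names = [c.column_name for c in self.columns]
        if len(set(names)) != len(names):
            raise StructureValidationError(
                f"database {self.name!r}: duplicate column names")
        locals_ = [c.predicate_local_name for c in self.columns]
        if len(set(locals_)) != len(locals_):
            raise StructureValidationError(
                f"database {self.name!r}: duplicate predicate local names")
        # depends_on resolves within this table and is acyclic
        by_name = {c.column_name: c for c in self.columns}
        for c in self.columns:
            if c.depends_on is None:
                continue
            if c.depends_on not in by_name:
                raise StructureValidationError(
                    f"database {self.name!r}, column {c.column_name!r}: "
                    f"depends_on target {c.depends_on!r} is not a column of "
                    "this table")
            seen = {c.column_name}
            cur = c.depends_on
            while cur is not None:
                if cur in seen:
                    raise StructureValidationError(
                        f"database {self.name!r}: dependency cycle through "
                        f"column {cur!r}")
                seen.add(cur)
                cur = by_name[cur].depends_on

    def column(self, column_name: str) -> ColumnSpec:
        for c in self.columns:
            if c.column_name == column_name:
                return c
        raise KeyError(column_name)

    def dependency_chain(self, column_name: str) -> list[ColumnSpec]:
        """Prerequisite columns of *column_name*, outermost (root) first."""
        chain: list[ColumnSpec] = []
        cur = self.column(column_name).depends_on
        while cur is not None:
            spec = self.column(cur)
            chain.append(spec)
            cur = spec.depends_on
        chain.reverse()
        return chain


@dataclass(frozen=True)
class CollectionSpec:
    """A named grouping of databases; has no rows or namespace of its own."""

    name: str
    parent: str | None = None


@dataclass
class DatabaseStructure:
    """The validated structure of a collection of databases."""

    databases: list[DatabaseSpec] = field(default_factory=list)
    collections: list[CollectionSpec] = field(default_factory=list)

    def __post_init__(self):
        names = [d.name for d in self.databases] + [c.name for c in self.collections]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise StructureValidationError(
                f"database/collection names must be unique; duplicated: "
                f"{sorted(dup)}")
        declared = set(names)
        for item in list(self.databases) + list(self.collections):
            if item.parent is not None and item.parent not in declared:
                raise StructureValidationError(
                    f"{item.name!r}: parent {item.parent!r} is not declared")
        # parent relation acyclic
        parent_of = {i.name: i.parent for i in
                     list(self.databases) + list(self.collections)}
        for start in parent_of:
            seen = set()
            cur = start
            while cur is not None:
                if cur in seen:
                    raise StructureValidationError(
                        f"parent cycle through {cur!r}")
                seen.add(cur)
                cur = parent_of.get(cur)

    # -- lookups -----------------------------------------------------------

    def database(self, name: str) -> DatabaseSpec:
        for d in self.databases:
            if d.name == name:
                return d
        raise KeyError(name)

    def database_for_subject(self, subject: str) -> DatabaseSpec | None:
        """The database owning *subject*, by longest namespace prefix."""
        best = None
        for d in self.databases:
            if subject.startswith(d.namespace):
                if best is None or len(d.namespace) > len(best.namespace):
                    best = d
        return best

    def predicate_iri(self, db: DatabaseSpec, col: ColumnSpec) -> URIRef:
        return URIRef(db.namespace + col.predicate_local_name)

    def column_for_predicate(self, predicate: str) -> tuple[DatabaseSpec, ColumnSpec] | None:
        for d in self.databases:
            for c in d.columns:
                if d.namespace + c.predicate_local_name == str(predicate):
                    return d, c
        return None

    def class_iri(self, name: str) -> URIRef:
        return STRUCT[name]


# ---------------------------------------------------------------------------
# Configuration parsing
# ---------------------------------------------------------------------------

_COLUMN_KEYS = {"column", "predicate", "display_name", "display_order",
                "hidden", "indexed", "datatype", "depends_on", "entity_type"}
_DATABASE_KEYS = {"name", "namespace", "parent", "columns"}
_COLLECTION_KEYS = {"name", "parent"}
_TOP_KEYS = {"databases", "collections"}


def _reject_unknown(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigParseError(
            f"{where}: unknown key(s) {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}")


def parse_structure_config(config_text: str) -> DatabaseStructure:
    """Parse a YAML structure configuration into a validated structure.

    Raises :class:`ConfigParseError` for malformed documents (with the YAML
    location when available) and :class:`StructureValidationError` for
    invariant violations, naming the offending entity.
    """
    try:
        doc = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        loc = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
        raise ConfigParseError(f"malformed configuration{loc}: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigParseError("top level of the configuration must be a mapping")
    _reject_unknown(doc, _TOP_KEYS, "top level")

    collections = []
    for i, entry in enumerate(doc.get("collections") or []):
        if not isinstance(entry, dict) or "name" not in entry:
            raise ConfigParseError(f"collections[{i}]: expected a mapping with a 'name'")
        _reject_unknown(entry, _COLLECTION_KEYS, f"collections[{i}]")
        collections.append(CollectionSpec(name=str(entry["name"]),
                                          parent=entry.get("parent")))

    databases = []
    for i, entry in enumerate(doc.get("databases") or []):
        if not isinstance(entry, dict) or "name" not in entry:
            raise ConfigParseError(f"databases[{i}]: expected a mapping with a 'name'")
        _reject_unknown(entry, _DATABASE_KEYS, f"databases[{i}]")
        name = str(entry["name"])
        if "namespace" not in entry:
            raise ConfigParseError(f"database {name!r}: missing 'namespace'")
        columns = []
        for j, col in enumerate(entry.get("columns") or []):
            if not isinstance(col, dict) or "column" not in col:
                raise ConfigParseError(
                    f"database {name!r}, columns[{j}]: expected a mapping "
                    "with a 'column'")
            _reject_unknown(col, _COLUMN_KEYS, f"database {name!r}, columns[{j}]")
            cname = str(col["column"])
            columns.append(ColumnSpec(
                column_name=cname,
                predicate_local_name=str(col.get("predicate", _sanitize_local(cname))),
                display_name=str(col.get("display_name", cname)),
                display_order=int(col.get("display_order", j)),
                hidden=bool(col.get("hidden", False)),
                indexed=bool(col.get("indexed", True)),
                datatype=str(col.get("datatype", "string")),
                depends_on=col.get("depends_on"),
                entity_type=col.get("entity_type"),
            ))
        databases.append(DatabaseSpec(name=name,
                                      namespace=str(entry["namespace"]),
                                      parent=entry.get("parent"),
                                      columns=tuple(columns)))
    return DatabaseStructure(databases=databases, collections=collections)


def _sanitize_local(name: str) -> str:
    """Default predicate local name: column header with illegal chars as '_'."""
    return re.sub(r"[^A-Za-z0-9_.\-~]", "_", name)


# ---------------------------------------------------------------------------
# RDFS schema emission
# ---------------------------------------------------------------------------

def emit_schema_triples(structure: DatabaseStructure) -> Graph:
    """Emit the RDFS description of *structure* as an RDF graph.

    Per database: an ``rdx:Database`` typing statement, an ``rdfs:Class``
    typing statement and an ``rdx:namespace`` attribute. Per collection: an
    ``rdfs:Class`` typing statement. Per parent link: ``rdfs:subClassOf``.
    Per column: one ``rdfs:domain`` statement plus attribute statements about
    the predicate (source column, display name, display order, hidden,
    indexed, datatype; entity type when declared), and one ``rdfs:seeAlso``
    dependent → prerequisite statement when the column depends on another.
    """
    g = Graph()
    g.bind("rdx", VOCAB)
    g.bind("rdfs", RDFS)
    for coll in structure.collections:
        cls = structure.class_iri(coll.name)
        g.add((cls, RDF.type, RDFS.Class))
        g.add((cls, VOCAB.name, Literal(coll.name)))
        if coll.parent is not None:
            g.add((cls, RDFS.subClassOf, structure.class_iri(coll.parent)))
    for db in structure.databases:
        cls = structure.class_iri(db.name)
        g.add((cls, RDF.type, VOCAB.Database))
        g.add((cls, RDF.type, RDFS.Class))
        g.add((cls, VOCAB.name, Literal(db.name)))
        g.add((cls, VOCAB.namespace, Literal(db.namespace)))
        if db.parent is not None:
            g.add((cls, RDFS.subClassOf, structure.class_iri(db.parent)))
        for col in db.columns:
            pred = structure.predicate_iri(db, col)
            g.add((pred, RDFS.domain, cls))
            g.add((pred, VOCAB.column, Literal(col.column_name)))
            g.add((pred, VOCAB.displayName, Literal(col.display_name)))
            g.add((pred, VOCAB.displayOrder, Literal(col.display_order)))
            g.add((pred, VOCAB.hidden, Literal(col.hidden)))
            g.add((pred, VOCAB.indexed, Literal(col.indexed)))
            g.add((pred, VOCAB.datatype, Literal(col.datatype)))
            if col.entity_type is not None:
                g.add((pred, VOCAB.entityType, Literal(col.entity_type)))
            if col.depends_on is not None:
                prereq = structure.predicate_iri(db, db.column(col.depends_on))
                g.add((pred, RDFS.seeAlso, prereq))
    return g


def schema_triple_count(structure: DatabaseStructure) -> int:
    """Closed-form size of :func:`emit_schema_triples` output."""
    n = 0
    for coll in structure.collections:
        n += 2 + (1 if coll.parent is not None else 0)
    for db in structure.databases:
        n += 4 + (1 if db.parent is not None else 0)
        for col in db.columns:
            n += 7  # domain + column + displayName + order + hidden + indexed + datatype
            if col.entity_type is not None:
                n += 1
            if col.depends_on is not None:
                n += 1
    return n


def parse_schema_graph(g: Graph) -> DatabaseStructure:
    """Recover a :class:`DatabaseStructure` from an emitted schema graph."""
    classes: dict[URIRef, str] = {}
    for cls in g.subjects(RDF.type, RDFS.Class):
        name = g.value(cls, VOCAB.name)
        classes[cls] = str(name) if name is not None else str(cls).rsplit("/", 1)[-1]
    db_classes = set(g.subjects(RDF.type, VOCAB.Database))

    def parent_name(cls):
        p = g.value(cls, RDFS.subClassOf)
        return classes.get(p) if p is not None else None

    collections = [CollectionSpec(name=classes[c], parent=parent_name(c))
                   for c in sorted(set(classes) - db_classes, key=str)]
    databases = []
    for cls in sorted(db_classes, key=str):
        ns = str(g.value(cls, VOCAB.namespace))
        preds = sorted(g.subjects(RDFS.domain, cls), key=str)
        pred_column = {p: str(g.value(p, VOCAB.column)) for p in preds}
        columns = []
        for p in preds:
            dep = g.value(p, RDFS.seeAlso)
            ent = g.value(p, VOCAB.entityType)
            columns.append(ColumnSpec(
                column_name=pred_column[p],
                predicate_local_name=str(p)[len(ns):],
                display_name=str(g.value(p, VOCAB.displayName)),
                display_order=int(g.value(p, VOCAB.displayOrder)),
                hidden=bool(g.value(p, VOCAB.hidden).toPython()),
                indexed=bool(g.value(p, VOCAB.indexed).toPython()),
                datatype=str(g.value(p, VOCAB.datatype)),
                depends_on=pred_column.get(dep),
                entity_type=str(ent) if ent is not None else None,
            ))
        columns.sort(key=lambda c: c.display_order)
        databases.append(DatabaseSpec(name=classes[cls], namespace=ns,
                                      parent=parent_name(cls),
                                      columns=tuple(columns)))
    return DatabaseStructure(databases=databases, collections=collections)


def canonical_ntriples(g: Graph) -> str:
    """Deterministic N-Triples serialization (sorted statement lines)."""
    lines = sorted(
        f"{s.n3()} {p.n3()} {o.n3()} ."
        for s, p, o in g
        if not isinstance(s, BNode) and not isinstance(o, BNode)
    )
    return "\n".join(lines) + ("\n" if lines else "")
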