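"""Key-query construction and execution over local or remote SPARQL stores.

Every search state — free text, raw SPARQL, facet value selections in any
combination — compiles to a single SPARQL query (the *key query*) whose
solution set is exactly the row subjects matching the state. Facet counting
is a second aggregate query that concatenates predicate and value with a
reserved separator string, groups, and counts; splitting the concatenation
on the first separator occurrence recovers each (facet, value) pair together
with its frequency in the current result.

Free text is resolved through the package's text index and embedded into
the key query as a ``VALUES`` block of matching subjects. Raw SPARQL must
project a ``?subject`` variable and is embedded as a subquery; federated
``SERVICE`` clauses inside it are passed through unmodified.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from rdflib import Graph, Literal, URIRef, Variable
from rdflib.plugins.sparql import prepareQuery
from rdflib.plugins.stores.sparqlstore import SPARQLStore

from .errors import (InconsistentCountsError, QueryContractError,
                     SeparatorCollisionError, TransportError)
from .schema import ColumnSpec, DatabaseSpec, DatabaseStructure
from .text_index import RetentionPolicy, SubjectHit, TextIndex

logger = logging.getLogger("rdfacets.sparql")

#: Default facet/value separator for the count-aggregation query. Any string
#: absent from all stored predicates and values works; collisions are
#: detected and reported.
DEFAULT_SEPARATOR = "⟂|⟂"


def _log_query(kind: str, query: str) -> None:
    logger.info(json.dumps({"event": "sparql", "kind": kind, "query": query}))


# ---------------------------------------------------------------------------
# Store abstraction
# ---------------------------------------------------------------------------

class Store:
    """A queryable triple store: an in-process graph or a remote endpoint."""

    def __init__(self, graph: Graph, endpoint: str | None = None):
        self.graph = graph
        self.endpoint = endpoint

    @classmethod
    def local(cls, source: Graph | str | Path) -> "Store":
        if isinstance(source, Graph):
            return cls(source)
        path = Path(source)
        fmt = "turtle" if path.suffix in (".ttl", ".turtle") else "nt"
        g = Graph()
        g.parse(path, format=fmt)
        return cls(g)

    @classmethod
    def remote(cls, endpoint_url: str) -> "Store":
        store = SPARQLStore(query_endpoint=endpoint_url, returnFormat="json")
        return cls(Graph(store=store), endpoint=endpoint_url)

    # rdflib's SPARQL connector reports unreachable endpoints as ValueError;
    # re-raise any transport-level failure with the endpoint identity.
    _TRANSPORT_ERRORS = (ConnectionError, OSError, IOError, ValueError)

    def query(self, sparql: str):
        try:
            return self.graph.query(sparql)
        except self._TRANSPORT_ERRORS as exc:
            if self.endpoint is not None:
                raise TransportError(self.endpoint, exc) from exc
            raise

    def predicate_objects(self, subject: URIRef):
        try:
            return list(self.graph.predicate_objects(subject))
        except self._TRANSPORT_ERRORS as exc:
            if self.endpoint is not None:
                raise TransportError(self.endpoint, exc) from exc
            raise


# ---------------------------------------------------------------------------
# Query specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FacetSelection:
    """Selected values of one facet.

    ``mode="any"`` (disjunctive): a subject matches if it holds at least one
    selected value. ``mode="all"`` (conjunctive): it must hold every selected
    value. Across facets, selections always combine conjunctively.
    """

    facet: str  # predicate IRI or column name (resolved against structure)
    values: frozenset[str]
    mode: str = "any"

    def __post_init__(self):
        if self.mode not in ("any", "all"):
            raise ValueError(f"mode must be 'any' or 'all', got {self.mode!r}")
        if not self.values:
            raise ValueError("a facet selection needs at least one value")


@dataclass
class QuerySpec:
    """One search state: free text and/or raw SPARQL plus facet selections.

    ``database`` restricts browsing to one database class; an empty
    selection list over a database is the browse mode that lists all of its
    rows and facets.
    """

    free_text: str | None = None
    raw_sparql: str | None = None
    selections: list[FacetSelection] = field(default_factory=list)
    policy: RetentionPolicy = field(default_factory=RetentionPolicy)
    database: str | None = None

    def validate(self) -> None:
        if (self.free_text is None and self.raw_sparql is None
                and not self.selections and self.database is None):
            raise QueryContractError(
                "a query needs free text, raw SPARQL, facet selections, or "
                "a database class to browse")


@dataclass(frozen=True)
class FacetValueCount:
    """One facet value with whole-database and in-result frequencies."""

    facet: str       # predicate IRI
    value: str       # stored facet value (dependent values keep their prefix)
    baseline_count: int
    query_count: int

    def __post_init__(self):
        if not (0 <= self.query_count <= self.baseline_count):
            raise InconsistentCountsError(
                f"facet {self.facet} value {self.value!r}: in-result count "
                f"{self.query_count} exceeds baseline {self.baseline_count}")


@dataclass(frozen=True)
class DisplayRecord:
    """One result row prepared for display: visible entries in display order."""

    subject: str
    database_name: str
    entries: tuple[tuple[str, str, str | None], ...]  # (display_name, value, entity_type)


@dataclass
class QueryResult:
    hits: list[SubjectHit]
    more_results: bool = False


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

_PREFIX_RE = re.compile(r"^\s*(PREFIX\s+\S+\s+<[^>]*>|BASE\s+<[^>]*>)\s*",
                        re.IGNORECASE | re.MULTILINE)


def validate_subject_contract(raw_sparql: str) -> None:
    """Reject user SPARQL that does not project a ``?subject`` variable.

    Malformed SPARQL raises the parser's own syntax error (with location);
    a well-formed query without ``?subject`` in its projection raises
    :class:`QueryContractError`.
    """
    prepared = prepareQuery(raw_sparql)
    projected = prepared.algebra.get("PV") or []
    if Variable("subject") not in projected:
        raise QueryContractError(
            "the SPARQL query must return a list of row subjects: it has to "
            "project a variable named ?subject")


def _split_prefixes(raw_sparql: str) -> tuple[str, str]:
    prefixes = "\n".join(m.group(1) for m in _PREFIX_RE.finditer(raw_sparql))
    body = _PREFIX_RE.sub("", raw_sparql).strip()
    return prefixes, body


class QueryEngine:
    """Faceted search over one converted store.

    Parameters
    ----------
    store:
        Local or remote :class:`Store` holding the data triples.
    structure:
        The database structure (predicates, display attributes, hierarchy).
    index:
        Text index for free-text queries; optional when only facet/SPARQL
        searches are used.
    separator:
        Reserved string for the facet-count aggregation query.
    """

    def __init__(self, store: Store, structure: DatabaseStructure,
                 index: TextIndex | None = None,
                 separator: str = DEFAULT_SEPARATOR):
        self.store = store
        self.structure = structure
        self.index = index
        self.separator = separator
        self._baseline_cache: dict[str, dict[tuple[str, str], int]] = {}
        self._separator_checked = False

    # -- helpers -----------------------------------------------------------

    def _resolve_facet(self, facet: str) -> tuple[DatabaseSpec, ColumnSpec]:
        hit = self.structure.column_for_predicate(facet)
        if hit is not None:
            return hit
        for db in self.structure.databases:
            for col in db.columns:
                if col.column_name == facet or col.predicate_local_name == facet:
                    return db, col
        raise QueryContractError(f"unknown facet {facet!r}")

    def _selection_literal(self, col: ColumnSpec, value: str) -> Literal:
        # Dependent facets store the colon-prefixed form as a plain string.
        if col.depends_on is not None or col.xsd_datatype is None:
            return Literal(value)
        return Literal(value, datatype=col.xsd_datatype)

    # -- key query ---------------------------------------------------------

    def build_key_query(self, spec: QuerySpec,
                        text_hits: list[str] | None = None) -> str:
        """Compile *spec* into the SPARQL key query returning ``?subject``.

        When *spec* has free text and *text_hits* is ``None``, the templated
        form with a text-query clause and the ``Search_Limit`` is returned
        (for display and auditing); during execution the text search is
        resolved through the index first and the hits are embedded as a
        ``VALUES`` block.
        """
        spec.validate()
        lines: list[str] = []
        prefixes = ""
        templated_text = False

        if spec.raw_sparql is not None:
            validate_subject_contract(spec.raw_sparql)
            prefixes, body = _split_prefixes(spec.raw_sparql)
            lines.append("  { " + body + " }")

        if spec.free_text is not None:
            if text_hits is None:
                templated_text = True
                lines.append(
                    f'  (?subject ?score) <http://jena.apache.org/text#query>'
                    f' {Literal(spec.free_text).n3()} .')
            else:
                values = " ".join(f"<{s}>" for s in text_hits) or "<urn:rdfacets:nohit>"
                lines.append(f"  VALUES ?subject {{ {values} }}")

        for k, sel in enumerate(spec.selections):
            db, col = self._resolve_facet(sel.facet)
            pred = self.structure.predicate_iri(db, col).n3()
            lits = sorted(self._selection_literal(col, v).n3()
                          for v in sel.values)
            if sel.mode == "any":
                var = f"?v{k}"
                lines.append(f"  ?subject {pred} {var} .")
                lines.append(f"  FILTER ( {var} IN ({', '.join(lits)}) )")
            else:
                for lit in lits:
                    lines.append(f"  ?subject {pred} {lit} .")

        if spec.database is not None:
            db = self.structure.database(spec.database)
            if not spec.selections and spec.free_text is None and spec.raw_sparql is None:
                lines.append("  ?subject ?p0 ?o0 .")
            lines.append(
                f'  FILTER ( STRSTARTS(STR(?subject), "{db.namespace}") )')

        head = "SELECT DISTINCT ?subject"
        if templated_text:
            head += " ?score"
        query = (prefixes + ("\n" if prefixes else "")
                 + head + "\nWHERE {\n" + "\n".join(lines) + "\n}")
        if templated_text:
            query += f"\nLIMIT {spec.policy.search_limit}"
        return query

    def _resolve_text(self, spec: QuerySpec):
        """Run the free-text part through the index; (hits, scores, more)."""
        if self.index is None:
            raise QueryContractError(
                "free-text search requires a text index; build one first")
        hits, more = self.index.search(spec.free_text, spec.policy)
        return hits, {h.subject: h.score for h in hits}, more

    def execute_key_query(self, spec: QuerySpec) -> QueryResult:
        """Execute the key query; subjects grouped by database.

        Free-text results are ordered by descending score (retention already
        applied); pure facet/SPARQL results are in subject-IRI order with a
        zero score.
        """
        spec.validate()
        scores: dict[str, float] = {}
        more = False
        text_hits = None
        if spec.free_text is not None:
            hits, scores, more = self._resolve_text(spec)
            text_hits = [h.subject for h in hits]
        query = self.build_key_query(spec, text_hits=text_hits)
        _log_query("key_query", query)
        subjects = sorted(str(row[0]) for row in self.store.query(query))

        def db_name(s: str) -> str:
            db = self.structure.database_for_subject(s)
            return db.name if db is not None else ""

        if spec.free_text is not None:
            subjects.sort(key=lambda s: (db_name(s), -scores.get(s, 0.0), s))
        else:
            subjects.sort(key=lambda s: (db_name(s), s))
        result = [SubjectHit(subject=s, score=scores.get(s, 0.0),
                             database_name=db_name(s))
                  for s in subjects]
        return QueryResult(hits=result, more_results=more)

    # -- facet counting ----------------------------------------------------

    def _check_separator(self) -> None:
        if self._separator_checked:
            return
        sep = self.separator.replace('"', '\\"')
        ask = ('ASK WHERE { ?s ?p ?v . FILTER ( '
               f'CONTAINS(STR(?v), "{sep}") || CONTAINS(STR(?p), "{sep}") ) }}')
        _log_query("separator_check", ask)
        if self.store.query(ask).askAnswer:
            raise SeparatorCollisionError(
                f"the separator {self.separator!r} occurs in stored values "
                "or predicate names; configure the engine with a different "
                "separator")
        self._separator_checked = True

    def _aggregate_counts(self, inner_where: str, prefixes: str = ""
                          ) -> dict[tuple[str, str], int]:
        sep = self.separator.replace('"', '\\"')
        query = (
            (prefixes + "\n" if prefixes else "")
            + "SELECT ?facetname (COUNT(*) AS ?total)\nWHERE {\n"
            + inner_where
            + f'\n  ?subject ?p ?v .\n'
              f'  BIND ( CONCAT(STR(?p), "{sep}", STR(?v)) AS ?facetname )\n'
              "}\nGROUP BY ?facetname")
        _log_query("facet_counts", query)
        counts: dict[tuple[str, str], int] = {}
        for row in self.store.query(query):
            facetname, total = str(row[0]), int(row[1])
            pred, value = facetname.split(self.separator, 1)
            counts[(pred, value)] = total
        return counts

    def baseline_counts(self, database_name: str) -> dict[tuple[str, str], int]:
        """Whole-database (facet value → frequency) map, cached per database."""
        if database_name not in self._baseline_cache:
            self._check_separator()
            db = self.structure.database(database_name)
            inner = (f'  ?subject ?p0 ?o0 .\n'
                     f'  FILTER ( STRSTARTS(STR(?subject), "{db.namespace}") )')
            inner = "  { SELECT DISTINCT ?subject WHERE {\n" + inner + "\n  } }"
            self._baseline_cache[database_name] = self._aggregate_counts(inner)
        return self._baseline_cache[database_name]

    def facet_counts(self, spec: QuerySpec, include_hidden: bool = False,
                     include_absent: bool = False) -> list[FacetValueCount]:
        """Facet values reachable from the result subjects, with counts.

        ``query_count`` is the value's frequency within the current result;
        ``baseline_count`` its frequency in the whole database. Hidden facets
        are excluded unless explicitly requested. With *include_absent*,
        baseline values missing from the result are added with
        ``query_count`` 0 (needed to measure under-representation).
        """
        spec.validate()
        self._check_separator()
        text_hits = None
        if spec.free_text is not None:
            hits, _, _ = self._resolve_text(spec)
            text_hits = [h.subject for h in hits]
        key_query = self.build_key_query(spec, text_hits=text_hits)
        # Hoist PREFIX/BASE declarations out of the subquery (illegal inside).
        prefixes, body = _split_prefixes(key_query)
        inner = "  { " + body.replace("\n", "\n    ") + " }"
        raw = self._aggregate_counts(inner, prefixes=prefixes)

        out: list[FacetValueCount] = []
        seen_dbs: set[str] = set()
        seen_facets: set[str] = set()
        for (pred, value), total in sorted(raw.items()):
            hit = self.structure.column_for_predicate(pred)
            if hit is None:
                continue
            db, col = hit
            seen_dbs.add(db.name)
            if col.hidden and not include_hidden:
                continue
            seen_facets.add(pred)
            baseline = self.baseline_counts(db.name).get((pred, value), 0)
            out.append(FacetValueCount(facet=pred, value=value,
                                       baseline_count=max(baseline, total),
                                       query_count=total))
        if include_absent:
            present = {(c.facet, c.value) for c in out}
            for db_name in sorted(seen_dbs):
                for (pred, value), baseline in sorted(
                        self.baseline_counts(db_name).items()):
                    if pred in seen_facets and (pred, value) not in present:
                        out.append(FacetValueCount(
                            facet=pred, value=value,
                            baseline_count=baseline, query_count=0))
        out.sort(key=lambda c: (c.facet, c.value))
        return out

    # -- record display ----------------------------------------------------

    def fetch_records(self, subjects: list[SubjectHit]) -> list[DisplayRecord]:
        """Display-ready records: visible entries only, in display order,
        labeled with display names and entity-type tags. Subjects absent from
        the store are omitted with a warning."""
        records = []
        for hit in subjects:
            pos = self.store.predicate_objects(URIRef(hit.subject))
            if not pos:
                logger.warning(json.dumps({
                    "event": "missing_subject", "subject": hit.subject}))
                continue
            entries = []
            for p, o in pos:
                resolved = self.structure.column_for_predicate(str(p))
                if resolved is None:
                    continue
                _, col = resolved
                if col.hidden:
                    continue
                entries.append((col.display_order, col.display_name, str(o),
                                col.entity_type))
            entries.sort(key=lambda e: (e[0], e[1], e[2]))
            records.append(DisplayRecord(
                subject=hit.subject, database_name=hit.database_name,
                entries=tuple((d, v, t) for _, d, v, t in entries)))
        return records
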