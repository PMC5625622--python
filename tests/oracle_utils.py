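"""Brute-force oracles for engine equivalence tests.

Everything here recomputes expected results directly from the source table
by row-wise filtering and group-by, independently of the RDF/SPARQL path.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

from rdfacets import DatabaseSpec, DatabaseStructure, TableSource
from rdfacets.convert import _valid_for_datatype
from rdfacets.text_index import default_tokenizer


def stored_value(db: DatabaseSpec, row: dict, column_name: str) -> str | None:
    """The literal the converter stores for one cell, or None if no triple."""
    raw = row.get(column_name, "")
    if raw == "":
        return None
    col = db.column(column_name)
    if not _valid_for_datatype(raw, col.datatype):
        return None
    prefixes = [row[p.column_name] for p in db.dependency_chain(column_name)
                if row.get(p.column_name, "")]
    return ":".join(prefixes + [raw])


def row_matches_selections(db: DatabaseSpec, row: dict, selections) -> bool:
    for sel in selections:
        col = _resolve(db, sel.facet)
        v = stored_value(db, row, col.column_name)
        if sel.mode == "any":
            if v is None or v not in sel.values:
                return False
        else:  # all: a cell holds one value, so every selected value must be it
            if v is None or any(v != want for want in sel.values):
                return False
    return True


def row_matches_text(db: DatabaseSpec, row: dict, token: str) -> bool:
    """Whether any indexed column's stored literal contains the token."""
    for col in db.columns:
        if not col.indexed:
            continue
        v = stored_value(db, row, col.column_name)
        if v is not None and token in default_tokenizer(v):
            return True
    return False


def _resolve(db: DatabaseSpec, facet: str):
    for col in db.columns:
        if facet in (col.column_name, col.predicate_local_name,
                     db.namespace + col.predicate_local_name):
            return col
    raise KeyError(facet)


def expected_subjects(table: TableSource, structure: DatabaseStructure,
                      selections=(), text_token: str | None = None
                      ) -> set[str]:
    db = structure.database(table.database_name)
    out = set()
    for i, row in enumerate(table.rows, start=1):
        if not row_matches_selections(db, row, selections):
            continue
        if text_token is not None and not row_matches_text(db, row, text_token):
            continue
        # a row with no stored cell at all produces no subject in the store
        if all(stored_value(db, row, h) is None for h in table.header):
            continue
        out.add(db.namespace + str(i))
    return out


def expected_facet_counts(table: TableSource, structure: DatabaseStructure,
                          subjects: set[str], include_hidden: bool = False
                          ) -> dict[tuple[str, str], int]:
    """(predicate IRI, stored value) -> frequency among the given subjects."""
    db = structure.database(table.database_name)
    counts: dict[tuple[str, str], int] = {}
    for i, row in enumerate(table.rows, start=1):
        if db.namespace + str(i) not in subjects:
            continue
        for col in db.columns:
            if col.hidden and not include_hidden:
                continue
            v = stored_value(db, row, col.column_name)
            if v is None:
                continue
            key = (db.namespace + col.predicate_local_name, v)
            counts[key] = counts.get(key, 0) + 1
    return counts


def exact_binom_pmf(k: int, n: int, p: Fraction) -> Fraction:
    """Exact rational binomial pmf, from factorials."""
    return comb(n, k) * p**k * (1 - p) ** (n - k)


def random_selections(rng: np.random.Generator, table: TableSource,
                      structure: DatabaseStructure, max_selections: int = 3):
    """Random facet selections drawing values that occur in the table."""
    from rdfacets import FacetSelection

    db = structure.database(table.database_name)
    n_sel = int(rng.integers(0, max_selections + 1))
    cols = list(db.columns)
    selections = []
    for _ in range(n_sel):
        col = cols[rng.integers(len(cols))]
        present = sorted({v for row in table.rows
                          if (v := stored_value(db, row, col.column_name))})
        if not present:
            continue
        k = int(rng.integers(1, min(3, len(present)) + 1))
        values = [present[j] for j in rng.choice(len(present), size=k,
                                                 replace=False)]
        mode = "any" if rng.random() < 0.7 else "all"
        selections.append(FacetSelection(facet=col.column_name,
                                         values=frozenset(values), mode=mode))
    return selections


def random_text_token(rng: np.random.Generator, table: TableSource,
                      structure: DatabaseStructure) -> str | None:
    """A token occurring in some indexed stored literal, or None."""
    db = structure.database(table.database_name)
    tokens = sorted({t
                     for row in table.rows for col in db.columns
                     if col.indexed
                     if (v := stored_value(db, row, col.column_name))
                     for t in default_tokenizer(v)})
    if not tokens:
        return None
    return tokens[rng.integers(len(tokens))]
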