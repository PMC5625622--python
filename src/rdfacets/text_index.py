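"""Inverted full-text index over indexed literals, keyed by row subject.

Only literals of columns marked ``indexed`` are searchable; each posting
stores the owning subject and the complete literal. Scoring is a standard
tf·idf sum over matched query tokens; the contract the engine relies on is
the ordering and retention behaviour, not absolute score values.

Retention follows the engine's free-text rules: at most ``search_limit``
best matches are kept (default 300), and among those, matches scoring below
``score_ratio`` of the top score (default 25%) are dropped. A flag reports
whether more hits existed beyond the limit.
"""

from __future__ import annotations

import json
import math
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

from rdflib import Graph, Literal

from .errors import EmptyQueryError
from .schema import DatabaseStructure

#: Default analyzer: lowercase, split on non-alphanumeric runs, no stemming.
_TOKEN_RE = re.compile(r"[0-9a-z]+")


def default_tokenizer(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class SubjectHit:
    """One text-search hit: a row subject with its match score."""

    subject: str
    score: float
    database_name: str


@dataclass(frozen=True)
class RetentionPolicy:
    """Best-match retention: hit cap, then relative score cutoff."""

    search_limit: int = 300
    score_ratio: float = 0.25

    def __post_init__(self):
        if self.search_limit < 1:
            raise ValueError("search_limit must be a positive integer")
        if not (0 < self.score_ratio <= 1):
            raise ValueError("score_ratio must be in (0, 1]")


def apply_retention(ranked: list[tuple[str, float]],
                    policy: RetentionPolicy
                    ) -> tuple[list[tuple[str, float]], bool]:
    """Apply the best-match retention rules to score-ranked candidates.

    The candidate list must be sorted by descending score. The cap is
    applied first, then the relative cutoff against the retained top score;
    the boolean reports whether candidates beyond the cap existed. The
    operation is idempotent.
    """
    more = len(ranked) > policy.search_limit
    kept = ranked[:policy.search_limit]
    if kept:
        cutoff = policy.score_ratio * kept[0][1]
        kept = [(s, sc) for s, sc in kept if sc >= cutoff]
    return kept, more


class TextIndex:
    """In-memory inverted index with JSON persistence."""

    def __init__(self, tokenizer: Callable[[str], list[str]] | None = None):
        self.tokenize = tokenizer or default_tokenizer
        # token -> {subject -> term frequency}
        self.postings: dict[str, dict[str, int]] = {}
        # subject -> (database name, stored literals)
        self.subjects: dict[str, tuple[str, list[str]]] = {}

    # -- construction ------------------------------------------------------

    def add_literal(self, subject: str, database_name: str, literal: str) -> None:
        entry = self.subjects.setdefault(subject, (database_name, []))
        entry[1].append(literal)
        for tok in self.tokenize(literal):
            self.postings.setdefault(tok, {}).setdefault(subject, 0)
            self.postings[tok][subject] += 1

    @property
    def n_literals(self) -> int:
        return sum(len(lits) for _, lits in self.subjects.values())

    # -- search ------------------------------------------------------------

    def _score(self, tokens: list[str]) -> dict[str, float]:
        n_subjects = max(len(self.subjects), 1)
        scores: dict[str, float] = {}
        for tok in tokens:
            posting = self.postings.get(tok)
            if not posting:
                continue
            idf = math.log(1.0 + n_subjects / len(posting))
            for subject, tf in posting.items():
                scores[subject] = scores.get(subject, 0.0) + tf * idf
        return scores

    def search(self, query: str, policy: RetentionPolicy = RetentionPolicy()
               ) -> tuple[list[SubjectHit], bool]:
        """Score-ranked subject hits for *query*, with retention applied.

        Returns ``(hits, more_results)`` where *more_results* reports whether
        hits beyond the cap existed. Ties are broken by subject IRI so the
        ordering is deterministic. Raises :class:`EmptyQueryError` when the
        query has no tokens.
        """
        tokens = self.tokenize(query)
        if not tokens:
            raise EmptyQueryError(f"query {query!r} is empty after tokenization")
        scores = self._score(tokens)
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        ranked, more = apply_retention(ranked, policy)
        hits = [SubjectHit(subject=s, score=sc,
                           database_name=self.subjects[s][0])
                for s, sc in ranked]
        return hits, more

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "postings": self.postings,
            "subjects": {s: {"database": db, "literals": lits}
                         for s, (db, lits) in self.subjects.items()},
        }

    @classmethod
    def from_dict(cls, d: dict, tokenizer=None) -> "TextIndex":
        idx = cls(tokenizer)
        idx.postings = {t: dict(p) for t, p in d["postings"].items()}
        idx.subjects = {s: (v["database"], list(v["literals"]))
                        for s, v in d["subjects"].items()}
        return idx

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path, tokenizer=None) -> "TextIndex":
        return cls.from_dict(json.loads(Path(path).read_text()), tokenizer)


def build_index(triples: Graph, structure: DatabaseStructure,
                tokenizer=None) -> TextIndex:
    """Index exactly the literals of indexed predicates, subject-keyed.

    Literals of predicates unknown to the structure are skipped with a
    warning; literals of declared-but-not-indexed predicates are silently
    absent from the index.
    """
    idx = TextIndex(tokenizer)
    for s, p, o in triples:
        if not isinstance(o, Literal):
            continue
        hit = structure.column_for_predicate(str(p))
        if hit is None:
            warnings.warn(f"predicate {p} not declared in structure; "
                          "literal not indexed", stacklevel=2)
            continue
        db, col = hit
        if not col.indexed:
            continue
        idx.add_literal(str(s), db.name, str(o))
    return idx


def star_rating(score: float, top_score: float) -> int:
    """Relative relevance as 1–5 stars: the score quantized into fifths of
    the top score. Presentation only; monotone in the score."""
    if top_score <= 0 or score <= 0:
        return 0
    return max(1, math.ceil(5.0 * min(score, top_score) / top_score))
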