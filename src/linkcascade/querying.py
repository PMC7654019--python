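"""The three retrieval modes: exact, semi-exact and fuzzy candidate queries.

Each mode turns one query record into a ranked candidate set drawn from the
inverted index:

* **exact** — every non-missing attribute of the query must match the stored
  record exactly;
* **semi-exact** — the union of the leave-one-out arrangements: candidates
  may differ from the query in at most one attribute;
* **fuzzy** — every term of a string or date attribute is expanded to all
  vocabulary terms within Damerau-Levenshtein similarity 0.5 (categorical
  and municipality-code terms stay exact), and any record holding an
  expanded term is eligible.

Candidates are ranked by the TF-IDF retrieval score, ties broken by
ascending record id, and capped at ``top_n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .comparators import damerau_levenshtein
from .indexing import IndexedDataset, term_vector, tokenize
from .schema import Record

__all__ = [
    "QueryConfig",
    "CandidateSet",
    "exact_query",
    "semi_exact_query",
    "fuzzy_term_match",
    "fuzzy_query",
    "query_string",
]

#: attribute kinds whose terms tolerate edit distance in fuzzy mode
_FUZZY_KINDS = ("string", "date")


@dataclass(frozen=True)
class QueryConfig:
    """Retrieval parameters: candidate-list size and fuzzy similarity floor."""

    top_n: int = 20
    fuzzy_min_similarity: float = 0.5

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if not (0.0 < self.fuzzy_min_similarity <= 1.0):
            raise ValueError("fuzzy_min_similarity must be in (0, 1]")


@dataclass
class CandidateSet:
    """Ranked retrieval result for one query record."""

    entries: list[tuple[str, float]] = field(default_factory=list)
    stage: str = ""

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __bool__(self) -> bool:
        return bool(self.entries)


def _rank(index: IndexedDataset, ids: set[str], query, cfg: QueryConfig,
          stage: str) -> CandidateSet:
    """Rank candidate ids by retrieval score (desc), tie by id, cap top_n."""
    scored = [(rid, index.retrieval_score(query, rid)) for rid in ids]
    scored.sort(key=lambda e: (-e[1], e[0]))
    return CandidateSet(entries=scored[: cfg.top_n], stage=stage)


def _equal_on(record: Record, b: Record, attributes) -> bool:
    return all(record.values.get(a, "") == b.values.get(a, "")
               for a in attributes)


def _seed_candidates(index: IndexedDataset, b: Record,
                     attributes: list[str]) -> set[str]:
    """Ids of records containing every term of each given attribute of b.

    A record equal to ``b`` on an attribute necessarily holds all of that
    attribute's terms, so intersecting postings is a complete pre-filter.
    """
    ids: set[str] | None = None
    for name in attributes:
        kind = index.schema.kind(name)
        for term in tokenize(b.values.get(name, ""), kind):
            posting = set(index.postings.get((name, term), ()))
            ids = posting if ids is None else ids & posting
            if not ids:
                return set()
    return ids if ids is not None else set(index.doc_store)


def exact_query(index: IndexedDataset, b: Record,
                cfg: QueryConfig) -> CandidateSet:
    """Records agreeing with ``b`` on every non-missing attribute of ``b``.

    Missing attributes of the query are dropped (not required to match).
    A fully missing query yields an empty candidate set.
    """
    non_missing = b.non_missing(index.schema)
    if not non_missing:
        return CandidateSet(stage="exact")
    ids = _seed_candidates(index, b, non_missing[:1])
    ids = {rid for rid in ids
           if _equal_on(index.doc_store[rid], b, non_missing)}
    return _rank(index, ids, term_vector(b, index.schema), cfg, "exact")


def semi_exact_query(index: IndexedDataset, b: Record,
                     cfg: QueryConfig) -> CandidateSet:
    """Union of the leave-one-out sub-queries over ``b``'s attributes.

    Every returned record differs from ``b`` in at most one non-missing
    attribute.  The schema needs at least two attributes for the n-1
    arrangement to exist.  With a single non-missing query attribute the
    constraint is vacuous and every indexed record is eligible (ranked and
    capped as usual).
    """
    if len(index.schema) < 2:
        raise ValueError("semi-exact query needs a schema with >= 2 attributes")
    non_missing = b.non_missing(index.schema)
    if not non_missing:
        return CandidateSet(stage="semi-exact")
    if len(non_missing) == 1:
        ids = set(index.doc_store)
    else:
        ids = set()
        for omit in non_missing:  # omit attributes in schema order
            kept = [a for a in non_missing if a != omit]
            sub = _seed_candidates(index, b, kept[:1])
            ids.update(rid for rid in sub
                       if _equal_on(index.doc_store[rid], b, kept))
    return _rank(index, ids, term_vector(b, index.schema), cfg, "semi-exact")


def fuzzy_term_match(query_term: str, vocab_term: str,
                     min_similarity: float) -> bool:
    """True iff the normalized Damerau-Levenshtein similarity clears the floor.

    Similarity is ``1 - DL(q, v) / max(|q|, |v|)``, measured against the
    longer term.
    """
    if not query_term or not vocab_term:
        return False
    longer = max(len(query_term), len(vocab_term))
    sim = 1.0 - damerau_levenshtein(query_term, vocab_term) / longer
    return sim >= min_similarity


def _expand_term(term: str, vocab: list[str], min_similarity: float) -> list[str]:
    """Vocabulary terms within the similarity floor of one query term.

    A length pre-filter skips terms whose length gap alone already exceeds
    the allowed edit distance.
    """
    matches = []
    lt = len(term)
    for v in vocab:
        longer = max(lt, len(v))
        if abs(lt - len(v)) > (1.0 - min_similarity) * longer:
            continue
        if fuzzy_term_match(term, v, min_similarity):
            matches.append(v)
    return matches


def fuzzy_query(index: IndexedDataset, b: Record,
                cfg: QueryConfig) -> CandidateSet:
    """Edit-tolerant retrieval: differences allowed on any attribute.

    Each term of a string or date attribute is expanded to the vocabulary
    terms passing :func:`fuzzy_term_match`; categorical and municipality-code
    terms are matched exactly even in fuzzy mode.  Any record holding an
    expanded term is a candidate, scored on the expanded term vector.
    """
    expanded: dict[str, list[str]] = {}
    ids: set[str] = set()
    for attr in index.schema:
        terms = term_vector(b, index.schema)[attr.name]
        if not terms:
            expanded[attr.name] = []
            continue
        if attr.kind in _FUZZY_KINDS:
            vocab = index.vocabulary(attr.name)
            matched: list[str] = []
            for t in terms:
                matched.extend(_expand_term(t, vocab, cfg.fuzzy_min_similarity))
            matched = sorted(set(matched))
        else:
            matched = [t for t in terms if (attr.name, t) in index.postings]
        expanded[attr.name] = matched
        ids |= index.candidates_for_terms(attr.name, matched)
    return _rank(index, ids, expanded, cfg, "fuzzy")


def query_string(b: Record, schema, fuzzy: bool = False) -> str:
    """Debug rendering of a query in a Lucene-like search-string syntax.

    Exact queries render as ``+name:"JOAO DA SILVA" +dob:"2018-01-01"``;
    fuzzy queries mark edit-tolerant terms with a trailing ``~``.
    """
    parts = []
    for attr in schema:
        v = b.values.get(attr.name, "")
        if not v:
            continue
        if fuzzy and attr.kind in _FUZZY_KINDS:
            marked = " ".join(t + "~" for t in tokenize(v, attr.kind))
            parts.append(f'{attr.name}:"{marked}"')
        else:
            parts.append(f'+{attr.name}:"{v}"')
    return " ".join(parts)
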