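"""Inverted-index blocking: tokenization, index construction and TF-IDF scoring.

The larger dataset (A) is indexed once; every record of the smaller dataset
(B) is then turned into a per-attribute term query and scored against the
postings, so only a handful of similar A records are ever compared in full.
TF is a term's count in a record's attribute field divided by the field
length; IDF is the natural log of the corpus size over the term's document
frequency, counted per attribute field.  The TF-IDF score is used only to
*rank* retrieval candidates — pair classification uses the typed comparators.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from pathlib import Path
from typing import Mapping

from .schema import AttributeSchema, Dataset, Record

__all__ = ["tokenize", "build_index", "IndexedDataset", "TermVector"]

#: TermVector: mapping attribute name -> ordered list of query terms
TermVector = Mapping[str, list[str]]


def tokenize(value: str, kind: str) -> list[str]:
    """Split one normalized value into index terms.

    String values split on spaces ("JOAO DA SILVA" -> [JOAO, DA, SILVA]);
    canonical dates split on hyphens ("2018-01-01" -> [2018, 01, 01]);
    categorical and municipality-code values are a single opaque term.
    Missing values produce no terms.
    """
    if not value:
        return []
    if kind == "string":
        return [t for t in value.split(" ") if t]
    if kind == "date":
        return [t for t in value.split("-") if t]
    return [value]


def term_vector(record: Record, schema: AttributeSchema) -> dict[str, list[str]]:
    """Tokenize every attribute of a record into a query term vector."""
    return {a.name: tokenize(record.values.get(a.name, ""), a.kind)
            for a in schema}


class IndexedDataset:
    """Inverted index plus document store over one dataset.

    Attributes
    ----------
    doc_count
        Number of indexed records (N in the IDF formula).
    postings
        ``(attribute, term) -> {record_id: term count}``.
    field_lengths
        ``(record_id, attribute) -> total term count of that field``.
    doc_store
        ``record_id -> Record`` for candidate verification and comparison.
    """

    def __init__(self, schema: AttributeSchema) -> None:
        self.schema = schema
        self.doc_count = 0
        self.postings: dict[tuple[str, str], dict[str, int]] = {}
        self.field_lengths: dict[tuple[str, str], int] = {}
        self.doc_store: dict[str, Record] = {}

    # -- construction --------------------------------------------------

    def add(self, record: Record) -> None:
        if record.record_id in self.doc_store:
            raise ValueError(f"record {record.record_id!r} already indexed")
        self.doc_store[record.record_id] = record
        self.doc_count += 1
        for attr in self.schema:
            terms = tokenize(record.values.get(attr.name, ""), attr.kind)
            if not terms:
                continue
            self.field_lengths[(record.record_id, attr.name)] = len(terms)
            for term, n in Counter(terms).items():
                self.postings.setdefault((attr.name, term), {})[
                    record.record_id] = n

    # -- scoring -------------------------------------------------------

    def tf(self, term: str, record_id: str, attribute: str) -> float:
        """Term frequency: count in the record's field / field length."""
        if record_id not in self.doc_store:
            raise KeyError(f"unknown record {record_id!r}")
        length = self.field_lengths.get((record_id, attribute), 0)
        if length == 0:
            return 0.0
        count = self.postings.get((attribute, term), {}).get(record_id, 0)
        return count / length

    def idf(self, term: str, attribute: str) -> float:
        """Inverse document frequency: ln(N / df); 0 for unseen terms."""
        df = len(self.postings.get((attribute, term), {}))
        if df == 0:
            return 0.0
        return math.log(self.doc_count / df)

    def retrieval_score(self, query: TermVector, record_id: str) -> float:
        """Mean tf·idf of the query terms in the record's matching fields.

        The sum of per-term tf·idf contributions is divided by the number of
        query terms; any monotone normalization preserves the ranking, which
        is the retrieval contract.
        """
        if record_id not in self.doc_store:
            raise KeyError(f"unknown record {record_id!r}")
        n_terms = sum(len(ts) for ts in query.values())
        if n_terms == 0:
            return 0.0
        total = 0.0
        for attribute, terms in query.items():
            for term in terms:
                idf = self.idf(term, attribute)
                if idf == 0.0:
                    continue  # unseen term or df == N: zero contribution
                total += self.tf(term, record_id, attribute) * idf
        return total / n_terms

    def vocabulary(self, attribute: str) -> list[str]:
        """All distinct terms indexed for one attribute field."""
        return [t for (a, t) in self.postings if a == attribute]

    def candidates_for_terms(self, attribute: str,
                             terms: list[str]) -> set[str]:
        """Union of record ids holding any of the given terms."""
        ids: set[str] = set()
        for term in terms:
            ids.update(self.postings.get((attribute, term), ()))
        return ids

    # -- portable serialization ---------------------------------------

    def save(self, path: str | Path) -> None:
        """Persist the index as JSON triples (attribute, term, postings)."""
        payload = {
            "doc_count": self.doc_count,
            "schema": [[a.name, a.kind, a.weight] for a in self.schema],
            "postings": [
                [attr, term, sorted(rows.items())]
                for (attr, term), rows in sorted(self.postings.items())
            ],
            "documents": [
                {"record_id": r.record_id, "values": r.values,
                 "extras": r.extras}
                for r in self.doc_store.values()
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "IndexedDataset":
        payload = json.loads(Path(path).read_text())
        schema = AttributeSchema([tuple(a) for a in payload["schema"]])
        idx = cls(schema)
        for doc in payload["documents"]:
            idx.add(Record(doc["record_id"], doc["values"],
                           doc.get("extras", {})))
        if idx.doc_count != payload["doc_count"]:
            raise ValueError("corrupt index file: document count mismatch")
        return idx


def build_index(A: Dataset) -> IndexedDataset:
    """Build the inverted index over dataset A (the blocking structure)."""
    if len(A) == 0:
        raise ValueError("cannot index an empty dataset")
    idx = IndexedDataset(A.schema)
    for record in A:
        idx.add(record)
    return idx
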