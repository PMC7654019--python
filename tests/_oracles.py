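"""Independent brute-force oracles used to cross-check the implementation.

Everything here recomputes quantities from first principles (definitional
recursions, exhaustive scans over all records) and deliberately shares no
code path with the package internals it checks.
"""

from __future__ import annotations

import math
from collections import Counter
from functools import lru_cache

from linkcascade.indexing import tokenize


@lru_cache(maxsize=None)
def dl_oracle(a: str, b: str) -> int:
    """Optimal-string-alignment distance straight from its recursive definition."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    cost = 0 if a[-1] == b[-1] else 1
    best = min(dl_oracle(a[:-1], b) + 1,
               dl_oracle(a, b[:-1]) + 1,
               dl_oracle(a[:-1], b[:-1]) + cost)
    if len(a) >= 2 and len(b) >= 2 and a[-1] == b[-2] and a[-2] == b[-1]:
        best = min(best, dl_oracle(a[:-2], b[:-2]) + 1)
    return best


def brute_force_scores(records, schema, query_terms: dict[str, list[str]]):
    """Per-record mean tf·idf of the query, recomputed from raw records.

    ``records``: iterable of Record; ``query_terms``: attribute -> terms.
    Returns {record_id: score}.
    """
    docs = {r.record_id: {a.name: tokenize(r.values.get(a.name, ""), a.kind)
                          for a in schema} for r in records}
    n_docs = len(docs)
    n_query = sum(len(ts) for ts in query_terms.values())
    scores = {}
    for rid, fields in docs.items():
        total = 0.0
        for attr, terms in query_terms.items():
            field = fields.get(attr, [])
            counts = Counter(field)
            for term in terms:
                df = sum(1 for other in docs.values()
                         if term in other.get(attr, []))
                if df == 0 or not field:
                    continue
                tf = counts[term] / len(field)
                idf = math.log(n_docs / df)
                total += tf * idf
        scores[rid] = total / n_query if n_query else 0.0
    return scores


def _non_missing(b, schema):
    return [a.name for a in schema if b.values.get(a.name, "")]


def exact_members(records, b, schema) -> set[str]:
    """Ids equal to b on every non-missing attribute of b (empty query -> none)."""
    names = _non_missing(b, schema)
    if not names:
        return set()
    return {r.record_id for r in records
            if all(r.values.get(n, "") == b.values[n] for n in names)}


def semi_exact_members(records, b, schema) -> set[str]:
    """Ids differing from b in at most one of b's non-missing attributes."""
    names = _non_missing(b, schema)
    if not names:
        return set()
    out = set()
    for r in records:
        diffs = sum(1 for n in names if r.values.get(n, "") != b.values[n])
        if diffs <= 1:
            out.add(r.record_id)
    return out


def fuzzy_members(records, b, schema, min_similarity: float = 0.5) -> set[str]:
    """Ids sharing at least one (possibly edit-tolerant) term with b.

    String and date terms match within normalized DL similarity
    ``min_similarity`` of the longer term; categorical and municipality-code
    terms must be identical.
    """
    fuzzy_kinds = ("string", "date")

    def term_match(q: str, v: str) -> bool:
        longer = max(len(q), len(v))
        return longer > 0 and 1.0 - dl_oracle(q, v) / longer >= min_similarity

    b_terms = {a.name: tokenize(b.values.get(a.name, ""), a.kind)
               for a in schema}
    out = set()
    for r in records:
        hit = False
        for a in schema:
            r_terms = tokenize(r.values.get(a.name, ""), a.kind)
            if not r_terms or not b_terms[a.name]:
                continue
            if a.kind in fuzzy_kinds:
                if any(term_match(q, v)
                       for q in b_terms[a.name] for v in r_terms):
                    hit = True
            else:
                if b_terms[a.name][0] in r_terms:
                    hit = True
            if hit:
                break
        if hit:
            out.add(r.record_id)
    return out


def best_pair_score(records, b, schema):
    """Exhaustive all-pairs maximum of the weighted typed score.

    Returns (best_id, best_score) with ties broken by ascending id, or
    (None, None) if no record is comparable.
    """
    from linkcascade.comparators import compare_pair, weighted_score

    best_id, best = None, None
    for r in sorted(records, key=lambda x: x.record_id):
        try:
            s = weighted_score(compare_pair(r, b, schema), schema)
        except ValueError:
            continue
        if best is None or s > best:
            best_id, best = r.record_id, s
    return best_id, best
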