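"""Per-type attribute similarity functions and the weighted final score.

Each attribute kind has its own comparator returning a score in [0, 1]:

* ``string``      — Jaro-Winkler similarity;
* ``date``        — Hamming agreement over the 8 digits of ``YYYYMMDD``;
* ``categorical`` — exact agreement (1/0);
* ``ibge``        — tiered geographic agreement on the 7-digit Brazilian
  municipality code (full code / same 2-digit state prefix / different).

Per-attribute scores are averaged with empirically chosen weights that encode
each attribute's discriminatory power; attributes missing on either side are
excluded from the mean by renormalizing the weights over the observed ones,
so absence is never conflated with disagreement.
"""

from __future__ import annotations

import re
from typing import Optional

from .schema import AttributeSchema, Record

__all__ = [
    "MISSING",
    "jaro_winkler",
    "damerau_levenshtein",
    "date_similarity",
    "categorical_similarity",
    "ibge_similarity",
    "compare_pair",
    "weighted_score",
]

#: marker for an attribute that could not be compared (missing on a side)
MISSING = None

#: Winkler prefix parameters: boost scale and maximum prefix length credited
_WINKLER_SCALE = 0.1
_WINKLER_MAX_PREFIX = 4

#: score awarded when only the state prefix of two municipality codes agrees
IBGE_STATE_TIER = 0.5

_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


def jaro_similarity(a: str, b: str) -> float:
    """Plain Jaro similarity (matching characters and transpositions)."""
    if a == b:
        return 1.0 if a else 0.0
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return 0.0
    window = max(la, lb) // 2 - 1
    if window < 0:
        window = 0
    match_a = [False] * la
    match_b = [False] * lb
    m = 0
    for i, ch in enumerate(a):
        lo = max(0, i - window)
        hi = min(lb, i + window + 1)
        for j in range(lo, hi):
            if not match_b[j] and b[j] == ch:
                match_a[i] = match_b[j] = True
                m += 1
                break
    if m == 0:
        return 0.0
    # count transpositions among matched characters in order
    bs = [b[j] for j in range(lb) if match_b[j]]
    t = 0
    k = 0
    for i in range(la):
        if match_a[i]:
            if a[i] != bs[k]:
                t += 1
            k += 1
    t //= 2
    return (m / la + m / lb + (m - t) / m) / 3.0


def jaro_winkler(a: str, b: str) -> float:
    """Jaro similarity boosted for a shared prefix (scale 0.1, cap 4 chars).

    Symmetric; 1.0 iff the strings are equal and non-empty; 0.0 when exactly
    one side is empty.  Empty-vs-empty is a missing-data situation handled
    upstream, and scores 0 here.
    """
    j = jaro_similarity(a, b)
    prefix = 0
    for ca, cb in zip(a, b):
        if ca != cb or prefix == _WINKLER_MAX_PREFIX:
            break
        prefix += 1
    return j + prefix * _WINKLER_SCALE * (1.0 - j)


def damerau_levenshtein(a: str, b: str) -> int:
    """Optimal-string-alignment edit distance.

    Minimal number of single-character insertions, deletions, substitutions
    and adjacent transpositions, with no substring edited twice (the
    restricted Damerau-Levenshtein variant used by Lucene's fuzzy matching).
    """
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ca = a[i - 1]
        for j in range(1, lb + 1):
            cost = 0 if ca == b[j - 1] else 1
            best = min(prev[j] + 1,        # deletion
                       cur[j - 1] + 1,     # insertion
                       prev[j - 1] + cost)  # substitution
            if (i > 1 and j > 1 and ca == b[j - 2] and a[i - 2] == b[j - 1]):
                best = min(best, prev2[j - 2] + 1)  # adjacent transposition
            cur[j] = best
        prev2, prev = prev, cur
    return prev[lb]


def date_similarity(a: str, b: str) -> float:
    """Hamming agreement over the digit strings of two canonical dates.

    Both inputs must be ``YYYY-MM-DD``; the score is the fraction of the 8
    digit positions of ``YYYYMMDD`` that agree.
    """
    if not (_DATE_RE.match(a) and _DATE_RE.match(b)):
        raise ValueError(f"non-canonical date(s): {a!r}, {b!r}")
    da = a.replace("-", "")
    db = b.replace("-", "")
    differing = sum(1 for x, y in zip(da, db) if x != y)
    return 1.0 - differing / 8.0


def categorical_similarity(a: str, b: str) -> float:
    """1 for agreement, 0 for disagreement (on normalized values)."""
    return 1.0 if a == b else 0.0


def ibge_similarity(a: str, b: str, state_tier: float = IBGE_STATE_TIER) -> float:
    """Tiered agreement on 7-digit municipality codes.

    1.0 for identical codes, ``state_tier`` (default 0.5) when only the
    2-digit state prefix agrees, 0.0 otherwise.  Malformed codes fall back to
    plain categorical equality on the raw text.
    """
    if len(a) != 7 or len(b) != 7 or not (a.isdigit() and b.isdigit()):
        return categorical_similarity(a, b)
    if a == b:
        return 1.0
    if a[:2] == b[:2]:
        return state_tier
    return 0.0


_DISPATCH = {
    "string": jaro_winkler,
    "categorical": categorical_similarity,
    "date": date_similarity,
    "ibge": ibge_similarity,
}


def compare_pair(a: Record, b: Record,
                 schema: AttributeSchema) -> dict[str, Optional[float]]:
    """Score every schema attribute of a candidate pair.

    Returns a mapping attribute name -> score in [0, 1], or :data:`MISSING`
    when either side's value is missing.
    """
    scores: dict[str, Optional[float]] = {}
    for attr in schema:
        va = a.values.get(attr.name, "")
        vb = b.values.get(attr.name, "")
        if not va or not vb:
            scores[attr.name] = MISSING
        else:
            scores[attr.name] = _DISPATCH[attr.kind](va, vb)
    return scores


def weighted_score(scores: dict[str, Optional[float]],
                   schema: AttributeSchema) -> float:
    """Weighted mean of the non-missing attribute scores.

    Weights are renormalized over the observed attributes, so a pair with a
    missing attribute is judged only on what both records actually carry.
    Raises if every attribute is missing (the pair is incomparable).
    """
    num = 0.0
    den = 0.0
    for attr in schema:
        s = scores.get(attr.name, MISSING)
        if s is MISSING:
            continue
        num += attr.weight * s
        den += attr.weight
    if den == 0.0:
        raise ValueError("no comparable attributes: all scores missing "
                         "(or all observed weights zero)")
    return num / den
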