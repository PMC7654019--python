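"""The linkage cascade: exact → semi-exact → fuzzy with early exit.

For each record of the smaller dataset (B) the three queries run in order of
increasing cost; at each stage the best candidate under the weighted typed
score is found, and if it clears the acceptance threshold the pair is kept
and later stages are skipped.  Records that never clear the threshold still
carry the best candidate and score seen, so the full score distribution is
available for ROC analysis.  A post-processing pass enforces a many-to-one
resolution: when several B records claim the same A record, only the
highest-scoring link survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .comparators import compare_pair, weighted_score
from .indexing import IndexedDataset, build_index
from .querying import (CandidateSet, QueryConfig, exact_query, fuzzy_query,
                       semi_exact_query)
from .schema import AttributeSchema, Dataset, Record

__all__ = [
    "STAGES",
    "LinkageConfig",
    "LinkedPair",
    "LinkageResult",
    "find_most_similar",
    "link_record",
    "link_datasets",
    "resolve_many_to_one",
]

#: cascade stages in execution order (cheapest first)
STAGES = ("exact", "semi-exact", "fuzzy")

_QUERY_FNS = {
    "exact": exact_query,
    "semi-exact": semi_exact_query,
    "fuzzy": fuzzy_query,
}


@dataclass(frozen=True)
class LinkageConfig:
    """Cascade parameters: acceptance threshold, retrieval config, stages."""

    threshold: float = 0.9
    query: QueryConfig = field(default_factory=QueryConfig)
    stages_enabled: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must be in [0, 1]")
        bad = [s for s in self.stages_enabled if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stage(s) {bad}; valid: {STAGES}")
        if not self.stages_enabled:
            raise ValueError("at least one stage must be enabled")


@dataclass
class LinkedPair:
    """Best-match decision for one B record.

    ``accepted`` means the score cleared the threshold (and survived the
    many-to-one resolution); unaccepted pairs retain the best candidate,
    score and stage seen for downstream threshold sweeps.
    """

    b_id: str
    a_id: Optional[str] = None
    score: Optional[float] = None
    stage: Optional[str] = None
    accepted: bool = False


@dataclass
class LinkageResult:
    """One :class:`LinkedPair` per B record plus run metadata."""

    pairs: list[LinkedPair]
    config: LinkageConfig
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def accepted_pairs(self) -> list[LinkedPair]:
        return [p for p in self.pairs if p.accepted]

    def __len__(self) -> int:
        return len(self.pairs)

    def summary(self) -> dict:
        """Deterministic machine-readable run summary."""
        return {
            "n_records": len(self.pairs),
            "n_accepted": len(self.accepted_pairs),
            "acceptance_rate": (len(self.accepted_pairs) / len(self.pairs)
                                if self.pairs else 0.0),
            "stage_counts": dict(self.stage_counts),
            "config": {
                "threshold": self.config.threshold,
                "top_n": self.config.query.top_n,
                "fuzzy_min_similarity": self.config.query.fuzzy_min_similarity,
                "stages_enabled": list(self.config.stages_enabled),
            },
        }


def find_most_similar(b: Record, candidates: CandidateSet,
                      index: IndexedDataset, schema: AttributeSchema,
                      ) -> tuple[Optional[str], Optional[float]]:
    """Best candidate under the weighted typed score; ties by ascending id.

    Returns ``(None, None)`` on an empty candidate set, and skips candidates
    that share no comparable attribute with ``b``.
    """
    best_id: Optional[str] = None
    best_score: Optional[float] = None
    for a_id in sorted(candidates.ids):
        a = index.doc_store[a_id]
        try:
            score = weighted_score(compare_pair(a, b, schema), schema)
        except ValueError:  # no comparable attributes
            continue
        if best_score is None or score > best_score:
            best_id, best_score = a_id, score
    return best_id, best_score


def link_record(b: Record, index: IndexedDataset, cfg: LinkageConfig,
                schema: AttributeSchema) -> LinkedPair:
    """Run the query cascade for one B record.

    Stages execute in order exact, semi-exact, fuzzy (cheapest first); the
    first stage whose best candidate scores at or above the threshold wins
    and the rest are skipped.  If no stage clears the threshold, the pair is
    returned unaccepted carrying the best score and stage seen.
    """
    best = LinkedPair(b_id=b.record_id)
    for stage in STAGES:
        if stage not in cfg.stages_enabled:
            continue
        candidates = _QUERY_FNS[stage](index, b, cfg.query)
        a_id, score = find_most_similar(b, candidates, index, schema)
        if score is None:
            continue
        if best.score is None or score > best.score:
            best.a_id, best.score, best.stage = a_id, score, stage
        if score >= cfg.threshold:
            return LinkedPair(b.record_id, a_id, score, stage, accepted=True)
    return best


def link_datasets(A: Dataset, B: Dataset,
                  cfg: LinkageConfig | None = None) -> LinkageResult:
    """Index dataset A, link every record of B through the cascade.

    Emits exactly one pair per B record (accepted or not) and applies the
    many-to-one resolution before returning.
    """
    cfg = cfg or LinkageConfig()
    if A.schema != B.schema:
        raise ValueError("datasets A and B must share the linkage schema")
    index = build_index(A)
    pairs = [link_record(b, index, cfg, A.schema) for b in B]
    stage_counts: dict[str, int] = {s: 0 for s in STAGES}
    for p in pairs:
        if p.accepted and p.stage:
            stage_counts[p.stage] += 1
    result = LinkageResult(pairs=pairs, config=cfg, stage_counts=stage_counts)
    return resolve_many_to_one(result)


def resolve_many_to_one(result: LinkageResult) -> LinkageResult:
    """Keep only the best link per A record among accepted pairs.

    When several B records are accepted against the same A record, the
    highest score wins (ties broken by ascending B id); the losers are
    demoted to unaccepted but keep their score and stage.
    """
    by_a: dict[str, list[LinkedPair]] = {}
    for p in result.pairs:
        if p.accepted and p.a_id is not None:
            by_a.setdefault(p.a_id, []).append(p)
    for claimants in by_a.values():
        if len(claimants) <= 1:
            continue
        claimants.sort(key=lambda p: (-p.score, p.b_id))
        for loser in claimants[1:]:
            loser.accepted = False
    return result
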