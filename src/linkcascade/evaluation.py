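"""Linkage-quality assessment: ground truth, confusion counts, ROC and tables.

Ground truth is established by an exact join on a shared unique key (the way
live-birth registration numbers flag true pairs between vital-statistics
systems).  Decisions are counted at the B-record level: each evaluated B
record yields exactly one decision at a given cutoff, so sensitivity,
specificity and PPV are all well defined, and a sweep over the observed
score distribution gives the ROC curve, its trapezoidal AUC and the
Youden-optimal cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .linkage import LinkageResult
from .schema import Dataset

__all__ = [
    "GroundTruth",
    "ConfusionCounts",
    "build_truth_by_key",
    "classify_at_threshold",
    "metrics",
    "threshold_table",
    "threshold_row_percentages",
    "roc_and_auc",
]


@dataclass(frozen=True)
class GroundTruth:
    """The set of true (b_id, a_id) pairs over an evaluated universe."""

    true_pairs: frozenset[tuple[str, str]]
    universe: int

    def __post_init__(self) -> None:
        b_ids = [b for b, _ in self.true_pairs]
        if len(set(b_ids)) != len(b_ids):
            dupes = sorted({b for b in b_ids if b_ids.count(b) > 1})
            raise ValueError(f"duplicate B ids in truth pairs: {dupes}")

    @property
    def by_b(self) -> dict[str, str]:
        return {b: a for b, a in self.true_pairs}

    def __len__(self) -> int:
        return len(self.true_pairs)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN tallies of B-record decisions at one cutoff."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def build_truth_by_key(A: Dataset, B: Dataset, key_column: str) -> GroundTruth:
    """True pairs from an exact-equality join on a shared unique key.

    The key may be a linkage attribute or an extra (non-linkage) column.
    Missing keys never join.  Duplicate keys within B are an error (each B
    record may have at most one true counterpart).
    """
    def key_of(record) -> str:
        return record.get(key_column).strip()

    for ds, name in ((A, "A"), (B, "B")):
        present = key_column in set(ds.schema.names) or any(
            key_column in r.extras for r in ds)
        if not present:
            raise ValueError(
                f"key column {key_column!r} absent from dataset {name}")

    a_by_key: dict[str, str] = {}
    for r in A:
        k = key_of(r)
        if k:
            a_by_key.setdefault(k, r.record_id)
    seen_b: dict[str, list[str]] = {}
    pairs = set()
    for r in B:
        k = key_of(r)
        if not k:
            continue
        seen_b.setdefault(k, []).append(r.record_id)
        if k in a_by_key:
            pairs.add((r.record_id, a_by_key[k]))
    dupes = sorted(k for k, ids in seen_b.items() if len(ids) > 1)
    if dupes:
        raise ValueError(f"duplicate key value(s) in dataset B: {dupes}")
    return GroundTruth(true_pairs=frozenset(pairs), universe=len(B))


def classify_at_threshold(result: LinkageResult, truth: GroundTruth,
                          cutoff: float) -> ConfusionCounts:
    """Confusion counts when links are accepted at ``score >= cutoff``.

    A pair linked (at the cutoff) to its true counterpart is a TP; linked to
    any other record an FP; a truth pair left unlinked an FN; and a B record
    with no true counterpart and no link a TN.
    """
    by_b = truth.by_b
    tp = fp = fn = tn = 0
    for p in result.pairs:
        linked = p.a_id is not None and p.score is not None and p.score >= cutoff
        true_a = by_b.get(p.b_id)
        if linked:
            if true_a is not None and p.a_id == true_a:
                tp += 1
            else:
                fp += 1
        else:
            if true_a is not None:
                fn += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(counts: ConfusionCounts) -> tuple[Optional[float], Optional[float],
                                              Optional[float]]:
    """(sensitivity %, specificity %, PPV %); ``None`` when undefined.

    sensitivity = 100·tp/(tp+fn); specificity = 100·tn/(tn+fp);
    PPV = 100·tp/(tp+fp).  A zero denominator yields ``None`` rather than 0.
    """
    def pct(num: int, den: int) -> Optional[float]:
        return 100.0 * num / den if den > 0 else None

    sens = pct(counts.tp, counts.tp + counts.fn)
    spec = pct(counts.tn, counts.tn + counts.fp)
    ppv = pct(counts.tp, counts.tp + counts.fp)
    return sens, spec, ppv


def threshold_row_percentages(matches: int, true_matches: int,
                              false_matches: int, missed: int,
                              evaluated: int) -> dict[str, float]:
    """Percentages as reported in a threshold-analysis table.

    ``matches_pct`` is of the evaluated universe; true/false-match
    percentages are of the accepted matches; the missed percentage is of all
    true pairs (tp + fn).
    """
    true_total = true_matches + missed
    return {
        "matches_pct": 100.0 * matches / evaluated if evaluated else float("nan"),
        "true_matches_pct": (100.0 * true_matches / matches
                             if matches else float("nan")),
        "false_matches_pct": (100.0 * false_matches / matches
                              if matches else float("nan")),
        "missed_pct": (100.0 * missed / true_total
                       if true_total else float("nan")),
    }


def threshold_table(result: LinkageResult, truth: GroundTruth,
                    cutoffs: Sequence[float]) -> pd.DataFrame:
    """Threshold-analysis table: one row per cutoff.

    Columns: cutoff, matches (and % of evaluated), true matches (and % of
    matches), false matches (and % of matches), missed true matches (and %
    of all true pairs), sensitivity and specificity (percent).
    """
    if len(cutoffs) == 0:
        raise ValueError("cutoffs must be non-empty")
    rows = []
    for cutoff in cutoffs:
        c = classify_at_threshold(result, truth, cutoff)
        sens, spec, _ = metrics(c)
        matches = c.tp + c.fp
        pcts = threshold_row_percentages(matches, c.tp, c.fp, c.fn, c.total)
        rows.append({
            "cutoff": cutoff,
            "matches": matches,
            "matches_pct": pcts["matches_pct"],
            "true_matches": c.tp,
            "true_matches_pct": pcts["true_matches_pct"],
            "false_matches": c.fp,
            "false_matches_pct": pcts["false_matches_pct"],
            "missed": c.fn,
            "missed_pct": pcts["missed_pct"],
            "sensitivity": sens,
            "specificity": spec,
        })
    return pd.DataFrame(rows)


def roc_and_auc(result: LinkageResult, truth: GroundTruth,
                ) -> tuple[list[tuple[float, float]], float, float]:
    """ROC sweep over all observed scores.

    Returns ``(points, auc, best_cutoff)`` where points are
    ``(1 - specificity, sensitivity)`` as fractions, AUC is by the
    trapezoidal rule over the curve closed at (0,0) and (1,1), and
    ``best_cutoff`` maximizes Youden's J = sensitivity + specificity - 1.
    """
    scores = sorted({p.score for p in result.pairs if p.score is not None},
                    reverse=True)
    pts: list[tuple[float, float]] = [(0.0, 0.0)]
    best_cutoff = float("nan")
    best_j = -np.inf
    for cutoff in scores:
        c = classify_at_threshold(result, truth, cutoff)
        sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
        spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 1.0
        pts.append((1.0 - spec, sens))
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_cutoff = j, cutoff
    pts.append((1.0, 1.0))
    pts = sorted(set(pts))
    xs = np.array([x for x, _ in pts])
    ys = np.array([y for _, y in pts])
    auc = float(np.trapezoid(ys, xs))
    return pts, auc, best_cutoff
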