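from __future__ import annotations

import numpy as np
import pytest

from linkcascade import (ConfusionCounts, Dataset, GroundTruth,
                         LinkageConfig, LinkageResult, LinkedPair, Record,
                         build_truth_by_key, classify_at_threshold,
                         link_datasets, metrics, roc_and_auc, threshold_table)
from linkcascade.evaluation import threshold_row_percentages
from linkcascade.synthgen import CorruptionConfig, make_truthed_pair

from conftest import make_record


def _result(pairs):
    return LinkageResult(pairs=pairs, config=LinkageConfig())


class TestBuildTruthByKey:
    def _ds(self, schema, ids_keys, prefix):
        recs = [make_record(f"{prefix}{i}", nid=k) if k is not None
                else make_record(f"{prefix}{i}")
                for i, k in ids_keys]
        return Dataset(schema, recs)

    def test_join_count(self, schema):
        A = self._ds(schema, [(i, f"K{i}") for i in range(10)], "a")
        B = self._ds(schema, [(i, f"K{i}" if i < 7 else f"X{i}")
                              for i in range(10)], "b")
        truth = build_truth_by_key(A, B, "nid")
        assert len(truth) == 7
        assert ("b0", "a0") in truth.true_pairs

    def test_no_shared_keys_empty(self, schema):
        A = self._ds(schema, [(1, "K1")], "a")
        B = self._ds(schema, [(1, "Z1")], "b")
        assert len(build_truth_by_key(A, B, "nid")) == 0

    def test_duplicate_b_key_listed(self, schema):
        A = self._ds(schema, [(1, "K1")], "a")
        B = self._ds(schema, [(1, "K1"), (2, "K1")], "b")
        with pytest.raises(ValueError, match="K1"):
            build_truth_by_key(A, B, "nid")

    def test_missing_key_column(self, schema):
        A = self._ds(schema, [(1, "K1")], "a")
        B = self._ds(schema, [(1, "K1")], "b")
        with pytest.raises(ValueError, match="dn"):
            build_truth_by_key(A, B, "dn")


class TestClassifyAtThreshold:
    TRUTH = GroundTruth(frozenset({("b1", "a1"), ("b2", "a2"),
                                   ("b3", "a3")}), universe=5)
    PAIRS = [
        LinkedPair("b1", "a1", 0.95, "exact", True),    # correct, high
        LinkedPair("b2", "a9", 0.92, "fuzzy", True),    # wrong target
        LinkedPair("b3", "a3", 0.70, "fuzzy", False),   # correct, low score
        LinkedPair("b4", "a4", 0.91, "exact", True),    # spurious link
        LinkedPair("b5", None, None, None, False),      # correctly unlinked
    ]

    def test_mixed_fixture_counts(self):
        # b1 TP; b2 linked to the wrong record -> FP; b3 below cutoff with a
        # true pair -> FN; b4 spurious link -> FP; b5 unlinked non-match -> TN
        c = classify_at_threshold(_result(self.PAIRS), self.TRUTH, 0.9)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 2, 1, 1)
        assert c.total == 5

    def test_lower_cutoff_recovers_low_scoring_true_pair(self):
        c = classify_at_threshold(_result(self.PAIRS), self.TRUTH, 0.5)
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 2, 0, 1)

    def test_nothing_passes_above_one(self):
        c = classify_at_threshold(_result(self.PAIRS), self.TRUTH, 1.01)
        assert c.tp == 0 and c.fp == 0
        assert c.fn == len(self.TRUTH)

    def test_all_correct_above_cutoff(self):
        pairs = [LinkedPair("b1", "a1", 0.99, "exact", True),
                 LinkedPair("b2", "a2", 0.98, "exact", True)]
        truth = GroundTruth(frozenset({("b1", "a1"), ("b2", "a2")}), 2)
        c = classify_at_threshold(_result(pairs), truth, 0.9)
        assert c.fp == 0 and c.fn == 0 and c.tp == 2

    def test_counts_match_per_record_enumeration(self):
        rng = np.random.default_rng(17)
        pairs, truth_pairs = [], set()
        for i in range(20):
            b, a = f"b{i}", f"a{i}"
            score = float(rng.random())
            is_true = rng.random() < 0.5
            linked_to = a if rng.random() < 0.7 else f"w{i}"
            pairs.append(LinkedPair(b, linked_to, score, "fuzzy",
                                    score >= 0.5))
            if is_true:
                truth_pairs.add((b, a))
        truth = GroundTruth(frozenset(truth_pairs), universe=20)
        cutoff = 0.5
        tp = fp = fn = tn = 0
        for p in pairs:  # independent per-record re-classification
            linked = p.score >= cutoff
            true_a = dict(truth_pairs).get(p.b_id)
            if linked and true_a == p.a_id:
                tp += 1
            elif linked:
                fp += 1
            elif true_a is not None:
                fn += 1
            else:
                tn += 1
        c = classify_at_threshold(_result(pairs), truth, cutoff)
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)


class TestMetrics:
    @pytest.mark.parametrize("tp, fn, expected_sens", [
        (11532, 929, 92.5),   # printed one-decimal sensitivities
        (12100, 361, 97.1),
        (10636, 1825, 85.4),
    ])
    def test_sensitivity_reproduces_reported_rows(self, tp, fn, expected_sens):
        sens, _, _ = metrics(ConfusionCounts(tp=tp, fp=0, fn=fn, tn=0))
        assert round(sens, 1) == expected_sens

    def test_perfect_ppv(self):
        _, _, ppv = metrics(ConfusionCounts(tp=10, fp=0, fn=2, tn=3))
        assert ppv == 100.0

    def test_zero_denominator_is_undefined_not_zero(self):
        sens, spec, ppv = metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=5))
        assert sens is None and ppv is None
        assert spec == 100.0


class TestThresholdTable:
    def test_percentage_conventions(self):
        pcts = threshold_row_percentages(matches=12661, true_matches=11532,
                                         false_matches=1129, missed=929,
                                         evaluated=29816)
        assert round(pcts["matches_pct"], 2) == 42.46
        assert round(pcts["true_matches_pct"], 2) == 91.08
        assert round(pcts["false_matches_pct"], 2) == 8.92
        assert round(pcts["missed_pct"], 2) == 7.46

    def test_true_match_pct_row(self):
        pcts = threshold_row_percentages(matches=10984, true_matches=10636,
                                         false_matches=348, missed=1825,
                                         evaluated=29816)
        assert round(pcts["true_matches_pct"], 2) == 96.83

    def test_perfect_links_give_hundred_percent_true(self):
        pairs = [LinkedPair(f"b{i}", f"a{i}", 0.95, "exact", True)
                 for i in range(4)]
        truth = GroundTruth(frozenset((f"b{i}", f"a{i}") for i in range(4)), 4)
        table = threshold_table(_result(pairs), truth, [0.5])
        assert table.loc[0, "true_matches_pct"] == 100.0
        assert table.loc[0, "sensitivity"] == 100.0

    def test_monotone_in_cutoff(self):
        cfg = CorruptionConfig(typo_rate=0.3, missing_rate=0.1, seed=8)
        tp = make_truthed_pair(120, 50, 0.7, cfg)
        result = link_datasets(tp.dataset_a, tp.dataset_b,
                               LinkageConfig(threshold=0.8))
        cutoffs = [0.5, 0.7, 0.8, 0.9, 0.95, 1.0]
        table = threshold_table(result, tp.truth, cutoffs)
        assert (table["matches"].diff().dropna() <= 0).all()
        assert (table["sensitivity"].diff().dropna() <= 0).all()
        # tp + fn constant across cutoffs
        totals = table["true_matches"] + table["missed"]
        assert totals.nunique() == 1
        assert totals.iloc[0] == len(tp.truth)

    def test_empty_cutoffs_rejected(self):
        truth = GroundTruth(frozenset(), 0)
        with pytest.raises(ValueError):
            threshold_table(_result([]), truth, [])


class TestRocAndAuc:
    def test_perfect_separation_auc_one(self):
        pairs = ([LinkedPair(f"b{i}", f"a{i}", 0.9 + i / 100, "exact", True)
                  for i in range(5)] +
                 [LinkedPair(f"c{i}", f"w{i}", 0.2 + i / 100, "fuzzy", False)
                  for i in range(5)])
        truth = GroundTruth(frozenset((f"b{i}", f"a{i}") for i in range(5)),
                            10)
        _, auc, best = roc_and_auc(_result(pairs), truth)
        assert auc == pytest.approx(1.0)
        assert 0.2 < best <= 0.95

    def test_curve_monotone_in_both_coordinates(self):
        cfg = CorruptionConfig(typo_rate=0.4, missing_rate=0.15, seed=4)
        tp = make_truthed_pair(100, 50, 0.6, cfg)
        result = link_datasets(tp.dataset_a, tp.dataset_b,
                               LinkageConfig(threshold=0.8))
        points, auc, _ = roc_and_auc(result, tp.truth)
        xs = [x for x, _ in points]
        ys = [y for _, y in points]
        assert xs == sorted(xs) and ys == sorted(ys)
        assert 0.0 <= auc <= 1.0

    def test_permuted_labels_hover_at_half(self):
        rng = np.random.default_rng(123)
        n = 400
        aucs = []
        for trial in range(10):
            pairs = [LinkedPair(f"b{i}", f"a{i}", float(rng.random()),
                                "fuzzy", False) for i in range(n)]
            chosen = rng.choice(n, size=n // 2, replace=False)
            truth = GroundTruth(frozenset((f"b{i}", f"a{i}")
                                          for i in chosen), n)
            _, auc, _ = roc_and_auc(_result(pairs), truth)
            aucs.append(auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_agrees_with_sklearn_on_clean_labels(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(9)
        n = 200
        labels = rng.random(n) < 0.4
        scores = np.where(labels, rng.normal(0.8, 0.1, n),
                          rng.normal(0.5, 0.15, n)).clip(0, 1)
        pairs = [LinkedPair(f"b{i}", f"a{i}", float(scores[i]), "fuzzy",
                            False) for i in range(n)]
        truth = GroundTruth(frozenset((f"b{i}", f"a{i}")
                                      for i in range(n) if labels[i]), n)
        _, auc, _ = roc_and_auc(_result(pairs), truth)
        expected = roc_auc_score(labels.astype(int), scores)
        assert auc == pytest.approx(expected, abs=1e-6)

    def test_degenerate_single_score(self):
        pairs = [LinkedPair("b1", "a1", 0.9, "exact", True),
                 LinkedPair("b2", "a9", 0.9, "exact", True)]
        truth = GroundTruth(frozenset({("b1", "a1")}), 2)
        _, auc, _ = roc_and_auc(_result(pairs), truth)
        assert 0.0 <= auc <= 1.0


def test_truth_duplicate_b_ids_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        GroundTruth(frozenset({("b1", "a1"), ("b1", "a2")}), 2)
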