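"""Split enumeration, cross-validation, model selection, metric conventions."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sarcomap as sm
from sarcomap.activation import ActivationMap
from sarcomap.errors import StageError


class TestCountLeaveKOut:
    def test_study_scale_count(self):
        assert sm.count_leave_k_out(24, 6) == 134_596

    def test_smallest_case(self):
        assert sm.count_leave_k_out(2, 1) == 2

    def test_matches_exhaustive_enumeration(self):
        assert sm.count_leave_k_out(6, 2) == 15
        for n in range(2, 13):
            for k in range(1, n):
                assert sm.count_leave_k_out(n, k) == \
                    sum(1 for _ in combinations(range(n), k))

    def test_symmetry(self):
        for n, k in [(24, 6), (10, 3), (7, 2)]:
            assert sm.count_leave_k_out(n, k) == sm.count_leave_k_out(n, n - k)

    def test_invalid_holdout_rejected(self):
        with pytest.raises(StageError):
            sm.count_leave_k_out(4, 4)


class TestEnumerateSplits:
    LABELS4 = {"a": "sRCC", "b": "sRCC", "c": "nsRCC", "d": "nsRCC"}

    def test_four_ids_lexicographic(self):
        splits = list(sm.enumerate_leave_k_out(["d", "c", "b", "a"], 2, self.LABELS4))
        held_out = [p.validation_ids for p in splits]
        assert held_out == [("a", "b"), ("a", "c"), ("a", "d"),
                            ("b", "c"), ("b", "d"), ("c", "d")]
        for p in splits:
            assert set(p.training_ids) | set(p.validation_ids) == {"a", "b", "c", "d"}
            assert not set(p.training_ids) & set(p.validation_ids)

    def test_balanced_flag_matches_brute_force(self):
        splits = list(sm.enumerate_leave_k_out(list("abcd"), 2, self.LABELS4))
        assert sum(p.balanced for p in splits) == 4
        for p in splits:
            val_classes = sorted(self.LABELS4[s] for s in p.validation_ids)
            expected = val_classes == ["nsRCC", "sRCC"]
            assert p.balanced == expected

    def test_study_scale_stream_length(self):
        ids = [f"s{i:02d}" for i in range(24)]
        labels = {s: ("sRCC" if i < 12 else "nsRCC") for i, s in enumerate(ids)}
        assert sum(1 for _ in sm.enumerate_leave_k_out(ids, 6, labels)) == 134_596

    def test_subsample_is_seeded_and_smaller(self):
        ids = [f"s{i}" for i in range(10)]
        labels = {s: "sRCC" for s in ids[:5]} | {s: "nsRCC" for s in ids[5:]}
        a = list(sm.enumerate_leave_k_out(ids, 3, labels, max_splits=20, seed=1))
        b = list(sm.enumerate_leave_k_out(ids, 3, labels, max_splits=20, seed=1))
        c = list(sm.enumerate_leave_k_out(ids, 3, labels, max_splits=20, seed=2))
        assert len(a) == 20
        assert a == b
        assert a != c


class TestConfusionMetrics:
    @pytest.mark.parametrize("cm,expected", [
        # reference rows: (TP, FP, FN, TN) -> (acc, FPR, FNR, PPV, NPV) in %
        ((3, 1, 2, 4), (70.0, 10.0, 20.0, 75.0, 66.67)),
        ((3, 1, 0, 2), (83.33, 16.67, 0.0, 75.0, 100.0)),
        ((8, 1, 0, 7), (93.75, 6.25, 0.0, 88.89, 100.0)),
    ])
    def test_cohort_rows(self, cm, expected):
        row = sm.confusion_metrics(sm.ConfusionMatrix(*cm))
        got = (row.accuracy, row.fpr, row.fnr, row.ppv, row.npv)
        assert tuple(round(v, 2) for v in got) == expected

    def test_perfect_prediction(self):
        row = sm.confusion_metrics(sm.ConfusionMatrix(tp=5, fp=0, fn=0, tn=5))
        assert (row.accuracy, row.fpr, row.fnr, row.ppv, row.npv) == \
            (100.0, 0.0, 0.0, 100.0, 100.0)

    def test_undefined_ppv_npv_flagged(self):
        row = sm.confusion_metrics(sm.ConfusionMatrix(tp=0, fp=0, fn=2, tn=3))
        assert row.ppv is None
        row = sm.confusion_metrics(sm.ConfusionMatrix(tp=2, fp=3, fn=0, tn=0))
        assert row.npv is None

    @given(tp=st.integers(0, 40), fp=st.integers(0, 40),
           fn=st.integers(0, 40), tn=st.integers(0, 40))
    @settings(max_examples=200, derandomize=True)
    def test_total_cohort_identity(self, tp, fp, fn, tn):
        """accuracy + FPR + FNR = 100 under the total-cohort convention."""
        if tp + fp + fn + tn == 0:
            return
        row = sm.confusion_metrics(sm.ConfusionMatrix(tp, fp, fn, tn))
        assert row.accuracy + row.fpr + row.fnr == pytest.approx(100.0)


def _separable_maps(n_per_class=4):
    """Each class shares a hot neuron block; per-subject variation is small,
    so any held-out subject stays nearest its own class prototype."""
    maps, labels = {}, {}
    for i in range(n_per_class):
        h = np.zeros(81, dtype=int)
        h[0], h[1], h[4 + i] = 50, 25, 5
        maps[f"s{i}"] = ActivationMap.from_hits(f"s{i}", h)
        labels[f"s{i}"] = "sRCC"
        h2 = np.zeros(81, dtype=int)
        h2[80], h2[79], h2[70 - i] = 50, 25, 5
        maps[f"n{i}"] = ActivationMap.from_hits(f"n{i}", h2)
        labels[f"n{i}"] = "nsRCC"
    return maps, labels


class TestCrossValidate:
    def test_separable_maps_all_splits_perfect(self):
        maps, labels = _separable_maps()
        splits = list(sm.enumerate_leave_k_out(list(maps), 2, labels,
                                               max_splits=10, seed=0))
        table = sm.cross_validate(maps, labels, sm.LvqConfig(epochs=30, seed=0),
                                  splits)
        assert (table["train_accuracy"] == 100.0).all()
        assert (table["val_accuracy"] == 100.0).all()

    def test_duplicate_split_identical_rows(self):
        maps, labels = _separable_maps()
        split = next(iter(sm.enumerate_leave_k_out(list(maps), 2, labels)))
        table = sm.cross_validate(maps, labels, sm.LvqConfig(epochs=10, seed=3),
                                  [split, split])
        assert table.iloc[0].equals(table.iloc[1])

    def test_missing_map_rejected(self):
        maps, labels = _separable_maps()
        split = sm.SplitPlan(training_ids=("s0", "ghost"),
                             validation_ids=("n0",), balanced=False)
        with pytest.raises(StageError, match="ghost"):
            sm.cross_validate(maps, labels, sm.LvqConfig(epochs=1), [split])

    def test_permutation_null_near_chance(self):
        """With labels carrying no signal, validation accuracy is at chance.

        The grand mean over independent label permutations sits within
        3 standard errors of 50%.  Averaging across permutations matters:
        split accuracies within one permuted cohort are correlated
        through the shared subjects, so a single permutation's mean can
        sit several points off 50 without indicating any defect.  Only
        class-balanced splits enter — in an unbalanced leave-k-out split
        the held-out class excess is mirrored by a training-side deficit,
        which biases a prototype classifier below chance on pure noise.
        """
        per_perm_means = []
        n_splits = 0
        for perm_seed in range(10):
            rng = np.random.default_rng(100 + perm_seed)
            maps, labels = {}, {}
            perm_classes = ["sRCC"] * 20 + ["nsRCC"] * 20
            rng.shuffle(perm_classes)
            for i in range(40):
                hits = rng.integers(0, 30, 81) + 1
                maps[f"p{i:02d}"] = ActivationMap.from_hits(f"p{i:02d}", hits)
                labels[f"p{i:02d}"] = perm_classes[i]
            splits = [p for p in sm.enumerate_leave_k_out(
                list(maps), 4, labels, max_splits=120, seed=perm_seed)
                if p.balanced]
            n_splits += len(splits)
            table = sm.cross_validate(
                maps, labels, sm.LvqConfig(epochs=20, seed=perm_seed), splits)
            per_perm_means.append(table["val_accuracy"].mean())
        assert n_splits >= 200
        means = np.asarray(per_perm_means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 50.0) <= 3 * se


class TestSelectModel:
    def _table(self):
        import pandas as pd
        rows = []
        for i in range(12):
            rows.append({
                "training_ids": f"t{i}", "validation_ids": f"v{i}",
                "balanced": i % 2 == 0,
                "train_accuracy": 90.0 if i < 8 else 70.0,
                "val_accuracy": 85.0 if i < 8 else 60.0,
            })
        return pd.DataFrame(rows)

    def test_threshold_filter(self):
        selected = sm.select_model(self._table(), threshold=83.0)
        assert len(selected) == 8

    def test_impossible_bar_empty(self):
        assert sm.select_model(self._table(), threshold=101.0) == []

    def test_balanced_filter_semantics(self):
        table = self._table()
        table["balanced"] = False
        assert sm.select_model(table, 83.0, require_balanced=True) == []

    def test_ordering_by_validation_then_training(self):
        import pandas as pd
        table = pd.DataFrame([
            {"training_ids": "a", "validation_ids": "x", "balanced": True,
             "train_accuracy": 90.0, "val_accuracy": 85.0},
            {"training_ids": "b", "validation_ids": "y", "balanced": True,
             "train_accuracy": 95.0, "val_accuracy": 90.0},
            {"training_ids": "c", "validation_ids": "z", "balanced": True,
             "train_accuracy": 99.0, "val_accuracy": 85.0},
        ])
        selected = sm.select_model(table, threshold=80.0)
        assert [p.training_ids[0] for p in selected] == ["b", "c", "a"]
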