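"""Scoring: accuracies, confusion matrices, weighted metrics, orderings."""

import random

import numpy as np
import pytest

from tnstager.evaluation import (
    ERROR_CATEGORIES,
    ErrorRecord,
    EvaluationError,
    read_gold_csv,
    score,
    stage_ordering_deltas,
    tabulate_errors,
)
from tnstager.types import N_LABELS, T_LABELS


def pairs(labels):
    """{id: (t, n)} from a list of 'T..N..' strings."""
    return {f"r{i}": (lab[: lab.index("N")], lab[lab.index("N") :]) for i, lab in enumerate(labels)}


class TestScore:
    def test_perfect_predictions(self):
        gold = pairs(["T1cN0", "T4N3", "T2aN2"])
        res = score(gold, gold)
        assert res.accuracy_t == res.accuracy_n == res.accuracy_tn == 1.0
        assert res.weighted["tn"]["f1"] == pytest.approx(1.0)

    def test_three_item_toy_hand_computed(self):
        # gold (A,A,B), pred (A,B,B) on the N scale:
        # accuracy 2/3; weighted precision = (2/3)*1 + (1/3)*(1/2) = 5/6
        gold = {"a": ("T1a", "N0"), "b": ("T1a", "N0"), "c": ("T1a", "N1")}
        pred = {"a": ("T1a", "N0"), "b": ("T1a", "N1"), "c": ("T1a", "N1")}
        res = score(pred, gold)
        assert res.accuracy_n == pytest.approx(2 / 3)
        assert res.weighted["n"]["precision"] == pytest.approx(5 / 6)
        # weighted recall = (2/3)*(1/2) + (1/3)*1 = 2/3
        assert res.weighted["n"]["recall"] == pytest.approx(2 / 3)

    def test_all_x_predictions_score_zero(self):
        gold = pairs(["T1cN0", "T4N3"])
        pred = {k: ("TX", "NX") for k in gold}
        res = score(pred, gold)
        assert res.accuracy_tn == 0.0
        assert res.x_predictions == {"t": 2, "n": 2}
        assert sum(res.deltas.values()) == 0  # X excluded from ordering tallies

    def test_confusion_marginals_balance(self):
        rng = random.Random(0)
        tn = [f"{t}{n}" for t in T_LABELS for n in N_LABELS]
        gold = pairs([rng.choice(tn) for _ in range(200)])
        pred = {k: (rng.choice(T_LABELS), rng.choice(N_LABELS)) for k in gold}
        res = score(pred, gold)
        for mat, g, p in [
            (res.confusion_tn, [t + n for t, n in gold.values()], [t + n for t, n in pred.values()]),
            (res.confusion_t, [t for t, _ in gold.values()], [t for t, _ in pred.values()]),
        ]:
            assert mat.to_numpy().sum() == 200
            for lab in mat.index:
                assert mat.loc[lab].sum() == g.count(lab)
                assert mat[lab].sum() == p.count(lab)

    def test_accuracy_tn_bounded_by_componentwise(self):
        rng = random.Random(4)
        tn = [f"{t}{n}" for t in T_LABELS for n in N_LABELS]
        gold = pairs([rng.choice(tn) for _ in range(300)])
        pred = {k: (rng.choice(T_LABELS), rng.choice(N_LABELS)) for k in gold}
        res = score(pred, gold)
        assert res.accuracy_tn <= min(res.accuracy_t, res.accuracy_n) + 1e-12

    def test_key_mismatch_raises(self):
        gold = pairs(["T1cN0", "T4N3"])
        pred = {"r0": ("T1c", "N0")}
        with pytest.raises(EvaluationError, match="r1"):
            score(pred, gold)

    def test_weighted_metrics_against_independent_reference(self):
        """score() must agree with a from-scratch support-weighted
        one-vs-rest computation to 1e-12 on random prediction sets."""
        rng = random.Random(123)
        tn = [f"{t}{n}" for t in T_LABELS for n in N_LABELS]
        for trial in range(100):
            n = rng.randrange(5, 60)
            gold_l = [rng.choice(tn) for _ in range(n)]
            pred_l = [rng.choice(tn) for _ in range(n)]
            gold = pairs(gold_l)
            pred = {k: v for k, v in zip(gold, pairs(pred_l).values())}
            res = score(pred, gold)
            ref = reference_weighted(gold_l, pred_l)
            for key in ("precision", "recall", "f1"):
                assert abs(res.weighted["tn"][key] - ref[key]) < 1e-12


def reference_weighted(gold, pred):
    """Independent support-weighted one-vs-rest precision/recall/F1."""
    labels = sorted(set(gold))
    total = len(gold)
    wp = wr = wf = 0.0
    for lab in labels:
        tp = sum(1 for g, p in zip(gold, pred) if g == lab and p == lab)
        fp = sum(1 for g, p in zip(gold, pred) if g != lab and p == lab)
        fn = sum(1 for g, p in zip(gold, pred) if g == lab and p != lab)
        support = tp + fn
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        w = support / total
        wp += w * precision
        wr += w * recall
        wf += w * f1
    return {"precision": wp, "recall": wr, "f1": wf}


class TestOrderingDeltas:
    @pytest.mark.parametrize(
        "gold,pred,expect",
        [
            (("T1c", "N2"), ("T1c", "N1"), {"n_understaged": 1}),
            (("T1b", "N0"), ("T2a", "N0"), {"t_overstaged": 1}),
            (("T2", "N1"), ("T2a", "N1"), {"t_overstaged": 1}),  # undivided T2 < T2a
            (("T3", "N3"), ("T3", "N3"), {}),
        ],
    )
    def test_single_pair(self, gold, pred, expect):
        deltas = stage_ordering_deltas({"r": pred}, {"r": gold})
        nonzero = {k: v for k, v in deltas.items() if v}
        assert nonzero == expect

    def test_shuffled_accuracy_matches_permutation_expectation(self):
        """Under label shuffling, expected accuracy is the sum of squared
        class frequencies."""
        rng = random.Random(8)
        labels = ["T1cN0"] * 50 + ["T4N2"] * 30 + ["T2bN3"] * 20
        gold = pairs(labels)
        freqs = np.array([50, 30, 20]) / 100
        expected = float((freqs**2).sum())
        accs = []
        for _ in range(1000):
            shuffled = labels[:]
            rng.shuffle(shuffled)
            pred = {k: v for k, v in zip(gold, pairs(shuffled).values())}
            accs.append(score(pred, gold).accuracy_tn)
        assert np.mean(accs) == pytest.approx(expected, abs=0.01)


class TestErrorRecords:
    def test_taxonomy_enforced(self):
        with pytest.raises(EvaluationError, match="unknown error category"):
            ErrorRecord("r1", "T", "gremlins")

    def test_tabulation(self):
        recs = [
            ErrorRecord("r1", "T", "reporter"),
            ErrorRecord("r2", "N", "reporter"),
            ErrorRecord("r3", "N", "context_complexity"),
        ]
        table = tabulate_errors(recs)
        assert table.loc["reporter", "total"] == 2
        assert table.loc["context_complexity", "N"] == 1
        assert list(table.index) == list(ERROR_CATEGORIES)

    def test_duplicate_gold_ids_rejected(self, tmp_path):
        p = tmp_path / "gold.csv"
        p.write_text("report_id,t,n\nr1,T1c,N0\nr1,T4,N3\n")
        with pytest.raises(EvaluationError, match="duplicate"):
            read_gold_csv(p)
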