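import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ganlink.evaluate import auprc, auroc, evaluate_fold, ndcg, summarize
from ganlink.network_io import PredictionRecord
from ganlink.predict import CoverageReport


def records_from(scored):
    """scored: list of (pair, confidence, is_positive)."""
    recs = [PredictionRecord(pair=p, confidence=c) for p, c, _ in scored]
    pos = {p for p, _, flag in scored if flag}
    recs.sort(key=lambda r: (-r.confidence, r.pair))
    return recs, pos


def brute_force_auroc(scored):
    pos = [c for _, c, f in scored if f]
    neg = [c for _, c, f in scored if not f]
    total = concordant = 0
    for p in pos:
        for n in neg:
            total += 1
            if p > n:
                concordant += 1
            elif p == n:
                concordant += 0.5
    return concordant / total


def brute_force_ap(scored):
    ranked = sorted(scored, key=lambda t: (-t[1], t[0]))
    n_pos = sum(1 for t in ranked if t[2])
    tp = 0
    ap = 0.0
    for rank, (_, _, flag) in enumerate(ranked, start=1):
        if flag:
            tp += 1
            ap += tp / rank
    return ap / n_pos


def pair(i):
    return (f"a{i:03d}", f"b{i:03d}")


class TestAUROC:
    def test_perfect_ordering(self):
        recs, pos = records_from(
            [(pair(0), 0.9, True), (pair(1), 0.8, True), (pair(2), 0.2, False)]
        )
        assert auroc(recs, pos) == 1.0

    def test_inverted_ordering(self):
        recs, pos = records_from(
            [(pair(0), 0.1, True), (pair(1), 0.8, False), (pair(2), 0.9, False)]
        )
        assert auroc(recs, pos) == 0.0

    def test_worked_three_quarters(self):
        """pos 0.9, neg 0.8, pos 0.7, neg 0.1: 3 of 4 pairs concordant."""
        scored = [
            (pair(0), 0.9, True), (pair(1), 0.8, False),
            (pair(2), 0.7, True), (pair(3), 0.1, False),
        ]
        recs, pos = records_from(scored)
        assert auroc(recs, pos) == 0.75
        assert brute_force_auroc(scored) == 0.75

    def test_undefined_without_both_classes(self):
        recs, pos = records_from([(pair(0), 0.5, True)])
        with pytest.raises(ValueError):
            auroc(recs, pos)

    @settings(max_examples=40, deadline=None)
    @given(
        labels=st.lists(st.booleans(), min_size=2, max_size=60),
        seed=st.integers(0, 10_000),
    )
    def test_matches_pair_counting_oracle(self, labels, seed):
        if not (any(labels) and not all(labels)):
            return
        rng = np.random.default_rng(seed)
        # quantized scores force ties through both code paths
        scored = [
            (pair(i), float(rng.integers(0, 6)) / 5, flag)
            for i, flag in enumerate(labels)
        ]
        recs, pos = records_from(scored)
        assert auroc(recs, pos) == pytest.approx(brute_force_auroc(scored))


class TestAUPRC:
    def test_all_positives_first(self):
        recs, pos = records_from(
            [(pair(0), 0.9, True), (pair(1), 0.8, True), (pair(2), 0.2, False)]
        )
        assert auprc(recs, pos) == 1.0

    def test_single_positive_second_of_two(self):
        recs, pos = records_from([(pair(0), 0.9, False), (pair(1), 0.5, True)])
        assert auprc(recs, pos) == 0.5

    def test_exceeds_prevalence_for_good_ranking(self):
        scored = [(pair(i), 1.0 - i / 20, i < 3) for i in range(20)]
        recs, pos = records_from(scored)
        assert auprc(recs, pos) >= len(pos) / len(recs)

    @settings(max_examples=40, deadline=None)
    @given(
        labels=st.lists(st.booleans(), min_size=2, max_size=60),
        seed=st.integers(0, 10_000),
    )
    def test_matches_step_curve_oracle(self, labels, seed):
        if not any(labels):
            return
        rng = np.random.default_rng(seed)
        scored = [
            (pair(i), round(float(rng.uniform()), 3), flag)
            for i, flag in enumerate(labels)
        ]
        # oracle assumes a strict ordering; skip tied scores
        if len({c for _, c, _ in scored}) != len(scored):
            return
        recs, pos = records_from(scored)
        assert auprc(recs, pos) == pytest.approx(brute_force_ap(scored))


class TestNDCG:
    def test_all_positives_top(self):
        recs, pos = records_from(
            [(pair(0), 0.9, True), (pair(1), 0.8, True), (pair(2), 0.2, False)]
        )
        assert ndcg(recs, pos) == pytest.approx(1.0)

    def test_single_positive_rank_two(self):
        recs, pos = records_from([(pair(0), 0.9, False), (pair(1), 0.5, True)])
        assert ndcg(recs, pos) == pytest.approx(1.0 / math.log2(3))

    def test_no_positives_zero(self):
        recs, _ = records_from([(pair(0), 0.9, False)])
        assert ndcg(recs, set()) == 0.0

    def test_agrees_with_sklearn_on_tie_free_lists(self, rng):
        from sklearn.metrics import ndcg_score

        scores = rng.permutation(np.linspace(0.01, 0.99, 40))
        labels = rng.integers(0, 2, size=40).astype(float)
        if labels.sum() == 0:
            labels[0] = 1.0
        scored = [(pair(i), float(s), bool(l)) for i, (s, l) in enumerate(zip(scores, labels))]
        recs, pos = records_from(scored)
        # sklearn normalizes by ideal DCG over the same list: identical
        # definition for binary gain without truncation
        expected = ndcg_score(labels[None, :], scores[None, :])
        assert ndcg(recs, pos) == pytest.approx(expected, abs=1e-9)


class TestMonotoneInvariance:
    def test_metrics_invariant_under_monotone_transform(self, rng):
        scores = rng.uniform(0.05, 0.95, size=50)
        labels = rng.integers(0, 2, size=50)
        if labels.sum() in (0, 50):
            labels[:2] = [0, 1]
        base = [(pair(i), float(s), bool(l)) for i, (s, l) in enumerate(zip(scores, labels))]
        squashed = [(p, float(c**3), f) for p, c, f in base]
        r1, p1 = records_from(base)
        r2, p2 = records_from(squashed)
        assert auroc(r1, p1) == pytest.approx(auroc(r2, p2))
        assert auprc(r1, p1) == pytest.approx(auprc(r2, p2))
        assert ndcg(r1, p1) == pytest.approx(ndcg(r2, p2))


class TestEvaluateFold:
    def make_fold(self):
        removed = {pair(0), pair(1), pair(9)}
        recs = [
            PredictionRecord(pair(0), 0.9),
            PredictionRecord(pair(1), 0.8),
            PredictionRecord(pair(2), 0.3),
            PredictionRecord(pair(3), 0.1),
        ]
        return recs, removed

    def test_top_ranked_positives_perfect(self):
        recs, removed = self.make_fold()
        rep = evaluate_fold(recs, removed)
        assert rep.auroc == 1.0
        assert rep.ndcg == 1.0

    def test_accounting_identity(self):
        recs, removed = self.make_fold()
        rep = evaluate_fold(recs, removed)
        unpredicted = len(removed) - rep.n_positives_scored
        assert rep.n_positives_scored + unpredicted == len(removed)
        assert rep.n_positives_scored == 2

    def test_strict_mode_appends_unscored_positives(self):
        recs, removed = self.make_fold()
        rep = evaluate_fold(recs, removed, strict=True)
        assert rep.n_candidates == len(recs) + 1
        # the appended zero-confidence positive hurts the ranking
        assert rep.auroc < 1.0

    def test_matches_brute_force_on_toy_fold(self, rng):
        scored = []
        for i in range(30):
            scored.append((pair(i), round(float(rng.uniform()), 6), bool(rng.integers(0, 2))))
        recs, pos = records_from(scored)
        rep = evaluate_fold(recs, pos)
        assert rep.auroc == pytest.approx(brute_force_auroc(scored))
        assert rep.auprc == pytest.approx(brute_force_ap(scored))

    def test_random_scores_near_half(self):
        """Random confidences on a balanced toy give AUROC ~ 0.5."""
        rng = np.random.default_rng(0)
        vals = []
        for trial in range(300):
            scored = [
                (pair(i), float(rng.uniform()), i % 2 == 0) for i in range(20)
            ]
            vals.append(brute_force_auroc(scored))
            recs, pos = records_from(scored)
            assert auroc(recs, pos) == pytest.approx(vals[-1])
        assert abs(np.mean(vals) - 0.5) < 0.02

    def test_summarize_means(self):
        cov = CoverageReport(1.0, 1.0, 0.0)
        reps = [
            evaluate_fold(*self.make_fold(), coverage=cov),
            evaluate_fold(*self.make_fold(), coverage=cov),
        ]
        s = summarize(reps)
        assert s["auroc"] == reps[0].auroc
        assert s["n_folds"] == 2
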