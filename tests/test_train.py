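"""Spy CV protocol: folds, metrics, early stopping, consensus, sweeps."""

import numpy as np
import pytest

from punet import losses, train
from punet.graph import LabelSet
from punet.train import ConsensusRanking, FoldResult, TrainConfig


def _labels(n_pos, n_total):
    return LabelSet(frozenset(range(n_pos)), frozenset(range(n_pos, n_total)))


class TestMakeFolds:
    def test_even_partition(self):
        folds = train.make_folds(_labels(10, 50), k=5, seed=1)
        spies = [f.spies for f in folds]
        assert all(len(s) == 2 for s in spies)
        assert frozenset().union(*spies) == frozenset(range(10))
        for a in range(5):
            for b in range(a + 1, 5):
                assert not spies[a] & spies[b]

    def test_remainder_rule(self):
        folds = train.make_folds(_labels(11, 50), k=5, seed=1)
        assert sorted(len(f.spies) for f in folds) == [2, 2, 2, 2, 3]

    def test_deterministic(self):
        f1 = train.make_folds(_labels(10, 50), 5, 3)
        f2 = train.make_folds(_labels(10, 50), 5, 3)
        assert [f.spies for f in f1] == [f.spies for f in f2]

    def test_spies_move_to_unlabeled(self):
        folds = train.make_folds(_labels(10, 50), 5, 1)
        for f in folds:
            assert f.spies <= f.effective_unlabeled
            assert not f.spies & f.train_positives

    def test_too_few_positives_fatal(self):
        with pytest.raises(ValueError):
            train.make_folds(_labels(3, 50), k=5, seed=0)

    def test_spy_splits_at_base_fraction_reproduce_folds(self):
        base = train.make_folds(_labels(11, 50), 5, 9)
        alt = train.make_spy_splits(_labels(11, 50), 0.2, 9, 5)
        assert [f.spies for f in base] == [f.spies for f in alt]


class TestSpyRecall:
    def test_fraction_above_threshold(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.1])
        assert train.spy_recall(scores, range(5)) == 0.8

    def test_all_recovered(self):
        assert train.spy_recall(np.array([0.9, 0.9]), [0, 1]) == 1.0

    def test_exactly_at_threshold_not_recovered(self):
        assert train.spy_recall(np.full(5, 0.5), range(5)) == 0.0

    def test_empty_spies_fatal(self):
        with pytest.raises(ValueError):
            train.spy_recall(np.array([0.9]), [])


class TestSurrogateF1:
    def test_perfect(self):
        # r=1 and q=prior => surrogate precision 1 => F1 = 1
        scores = np.array([0.9, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1])
        assert train.surrogate_f1(scores, [0], prior=0.1) == pytest.approx(1.0)

    def test_zero_recall(self):
        assert train.surrogate_f1(np.array([0.1, 0.9]), [0], 0.1) == 0.0

    def test_hand_value(self):
        # r=0.8, q=0.2, prior=0.1 -> p*=0.4 -> F1 = 2*.4*.8/1.2 = 0.5333
        scores = np.zeros(50)
        scores[:10] = 0.9      # q = 0.2
        spies = list(range(8)) + [40, 41]  # 8 of 10 spies above
        assert train.surrogate_f1(scores, spies, 0.1) == pytest.approx(
            0.53333, abs=1e-4)


class TestConsensusRank:
    def _fr(self, scores, recall):
        return FoldResult(np.asarray(scores, float), recall, recall, 1, [])

    def test_recall_weighted_hand_value(self):
        labels = LabelSet(frozenset({1}), frozenset({0}))
        frs = [self._fr([0.9, 0.0], 1.0), self._fr([0.6, 0.0], 0.5)]
        ranking = train.consensus_rank(frs, labels, ("N0", "N1"))
        assert ranking.entries == [("N0", pytest.approx(0.8))]

    def test_equal_weights_plain_mean(self):
        labels = LabelSet(frozenset({2}), frozenset({0, 1}))
        frs = [self._fr([0.2, 0.6, 0.0], 0.7), self._fr([0.4, 0.2, 0.0], 0.7)]
        ranking = train.consensus_rank(frs, labels, ("A", "B", "C"))
        assert dict(ranking.entries) == {
            "A": pytest.approx(0.3), "B": pytest.approx(0.4)}

    def test_single_fold_verbatim(self):
        labels = LabelSet(frozenset({0}), frozenset({1, 2}))
        frs = [self._fr([0.9, 0.3, 0.8], 0.6)]
        ranking = train.consensus_rank(frs, labels, ("A", "B", "C"))
        assert ranking.entries == [("C", pytest.approx(0.8)),
                                   ("B", pytest.approx(0.3))]

    def test_ties_broken_by_node_id(self):
        labels = LabelSet(frozenset({2}), frozenset({0, 1}))
        frs = [self._fr([0.4, 0.4, 0.0], 1.0)]
        ranking = train.consensus_rank(frs, labels, ("B", "A", "C"))
        assert [n for n, _ in ranking.entries] == ["A", "B"]

    def test_all_zero_recall_fatal(self):
        labels = LabelSet(frozenset({0}), frozenset({1}))
        with pytest.raises(ValueError, match="no informative folds"):
            train.consensus_rank([self._fr([0.5, 0.5], 0.0)], labels, ("A", "B"))


class TestTopKUnion:
    def _ranking(self, names):
        return ConsensusRanking([(n, 1.0 - i * 0.01) for i, n in enumerate(names)],
                                (1.0,))

    def test_identical_rankings(self):
        r = self._ranking([f"N{i}" for i in range(10)])
        union, votes = train.top_k_union({"a": r, "b": r, "c": r, "d": r}, k=5)
        assert len(union) == 5
        assert all(votes[n] == {"a", "b", "c", "d"} for n in union)

    def test_disjoint_rankings(self):
        rankings = {m: self._ranking([f"{m}{i}" for i in range(6)])
                    for m in "abcd"}
        union, votes = train.top_k_union(rankings, k=5)
        assert len(union) == 20
        assert all(len(v) == 1 for v in votes.values())

    def test_short_ranking_fatal(self):
        with pytest.raises(ValueError):
            train.top_k_union({"a": self._ranking(["N1", "N2"])}, k=5)


class TestRecallAtK:
    def test_bounds(self):
        r = ConsensusRanking([(f"N{i}", 1 - i * 0.01) for i in range(20)], (1.0,))
        assert train.recall_at_k(r, {"N0", "N1"}, 5) == 1.0
        assert train.recall_at_k(r, {"N18", "N19"}, 5) == 0.0
        assert train.recall_at_k(r, {"N0", "N19"}, 20) == 1.0

    def test_empty_targets_fatal(self):
        r = ConsensusRanking([("N0", 0.9)], (1.0,))
        with pytest.raises(ValueError):
            train.recall_at_k(r, set(), 1)


class TestTrainFold:
    def test_patience_stops_after_constant_recall(self, small_instance,
                                                  monkeypatch):
        monkeypatch.setattr(train, "spy_recall", lambda *a, **k: 0.7)
        folds = train.make_folds(small_instance.labels, 5, 0)
        fr = train.train_fold(small_instance.network, small_instance.features,
                              folds[0], train_cfg=TrainConfig(seed=0))
        # 1 improving evaluation + 10 non-improving epochs
        assert fr.stopped_epoch == 11

    def test_deterministic_given_seed(self, small_instance):
        folds = train.make_folds(small_instance.labels, 5, 0)
        cfg = TrainConfig(seed=0, max_epochs=15, patience=5)
        f1 = train.train_fold(small_instance.network, small_instance.features,
                              folds[0], train_cfg=cfg)
        f2 = train.train_fold(small_instance.network, small_instance.features,
                              folds[0], train_cfg=cfg)
        assert np.array_equal(f1.scores, f2.scores)
        assert f1.spy_recall == f2.spy_recall

    def test_train_recall_at_least_spy_recall(self, small_instance):
        # overfitting direction: training positives are recovered at least
        # as well as withheld spies
        folds = train.make_folds(small_instance.labels, 5, 0)
        fr = train.train_fold(small_instance.network, small_instance.features,
                              folds[0], train_cfg=TrainConfig(seed=0))
        assert fr.train_recall >= fr.spy_recall - 0.15


class TestSweep:
    def test_single_point_matches_plain_run(self, small_instance):
        inst = small_instance
        tc = TrainConfig(seed=0, max_epochs=20, patience=5)
        table = train.sensitivity_sweep("prior", [0.1], inst.network,
                                        inst.features, inst.labels,
                                        train_cfg=tc, top_k=30)
        res = train.run_cv(inst.network, inst.features, inst.labels,
                           loss_cfg=losses.PULossConfig(prior=0.1),
                           train_cfg=tc)
        assert table.loc[0, "mean_recall"] == pytest.approx(res.mean_spy_recall)

    def test_unknown_axis_rejected(self, small_instance):
        with pytest.raises(ValueError):
            train.sensitivity_sweep("nonsense", [1], small_instance.network,
                                    small_instance.features,
                                    small_instance.labels)
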