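"""The four PU objectives: frozen hand-computed values, invariants, gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from punet import losses
from punet.graph import PPINetwork
from punet.losses import PULossConfig


class TestPointwiseLoss:
    @pytest.mark.parametrize("p,y,expected", [
        (0.5, 1, np.log(2)),
        (0.5, 0, np.log(2)),
        (1.0, 0, -np.log(1e-7)),  # clipping caps the blow-up at ~16.118
    ])
    def test_hand_values(self, p, y, expected):
        assert losses.pointwise_loss(p, y, 1e-7) == pytest.approx(expected, rel=1e-9)


class TestGeneralizedRisk:
    def test_all_half_scores_give_ln2_any_prior(self):
        for prior in (0.01, 0.1, 0.5, 0.9):
            bd, _ = losses.generalized_pu_risk([0.5] * 3, [0.5] * 7, prior)
            assert bd.total == pytest.approx(np.log(2), abs=1e-9)

    def test_zero_prior_is_unlabeled_as_negative(self):
        scores_u = [0.2, 0.3, 0.4]
        bd, _ = losses.generalized_pu_risk([0.9], scores_u, prior=0.0)
        expected = np.mean([-np.log(1 - s) for s in scores_u])
        assert bd.total == pytest.approx(expected, rel=1e-12)

    def test_hand_value(self):
        # P all 0.8, U all 0.3, prior 0.1:
        # 0.1*(-ln .8) + (-ln .7) - 0.1*(-ln .2) = 0.21804
        bd, _ = losses.generalized_pu_risk([0.8, 0.8], [0.3, 0.3, 0.3], 0.1)
        assert bd.total == pytest.approx(0.218046, abs=1e-5)

    def test_can_be_negative_while_nnpu_cannot(self):
        # confident positives + moderate unlabeled at a high prior drive the
        # surrogate negative risk below zero
        scores_p = [0.999]
        scores_u = [0.5, 0.5]
        bd, _ = losses.generalized_pu_risk(scores_p, scores_u, prior=0.9)
        nn, _ = losses.nnpu_loss(scores_p, scores_u, prior=0.9)
        assert bd.total < 0
        assert nn.total >= 0
        assert nn.correction_applied


class TestNnpu:
    def test_equals_generalized_risk_when_surrogate_nonnegative(self):
        scores_p, scores_u, prior = [0.8, 0.7], [0.2, 0.3, 0.4], 0.1
        bd, _ = losses.generalized_pu_risk(scores_p, scores_u, prior)
        nn, _ = losses.nnpu_loss(scores_p, scores_u, prior)
        assert bd.surrogate_negative_risk >= 0
        assert nn.total == pytest.approx(bd.total, rel=1e-12)
        assert not nn.correction_applied

    def test_clamp_drops_negative_term(self):
        nn, _ = losses.nnpu_loss([0.999], [0.5, 0.5], prior=0.9)
        expected_pos = 0.9 * -np.log(0.999)
        assert nn.total == pytest.approx(expected_pos, rel=1e-9)

    @given(st.lists(st.floats(0.01, 0.99), min_size=1, max_size=8),
           st.lists(st.floats(0.01, 0.99), min_size=1, max_size=8),
           st.floats(0.01, 0.99))
    @settings(max_examples=100, deadline=None)
    def test_nonnegative_and_finite(self, sp, su, prior):
        bd, g = losses.nnpu_loss(sp, su, prior)
        assert bd.total >= 0
        assert np.isfinite(bd.total)
        assert np.all(np.isfinite(g["p"])) and np.all(np.isfinite(g["u"]))

    def test_permutation_invariance(self, rng):
        sp = rng.uniform(0.1, 0.9, 5)
        su = rng.uniform(0.1, 0.9, 9)
        t1 = losses.nnpu_loss(sp, su, 0.2)[0].total
        t2 = losses.nnpu_loss(sp[::-1], rng.permutation(su), 0.2)[0].total
        assert t1 == pytest.approx(t2, rel=1e-12)


class TestDistpu:
    def cfg(self, **kw):
        return PULossConfig(loss_name="distpu", **kw)

    def test_alignment_zero_when_mean_matches_prior(self):
        bd, _ = losses.distpu_loss([0.9], [0.1, 0.1], None, 0.1, self.cfg())
        assert bd.auxiliary_terms["alignment"] == pytest.approx(0.0, abs=1e-12)

    def test_entropy_vanishes_at_extremes(self):
        eps = 1e-7
        bd, _ = losses.distpu_loss([0.9], [eps, 1 - eps], None, 0.5, self.cfg())
        assert bd.auxiliary_terms["entropy"] == pytest.approx(0.0, abs=1e-5)

    def test_hand_value(self):
        # P=(0.9), U=(0.2,0.4), prior 0.1, lambda_entropy 0.1, no mixup:
        # -ln.9 + |0.3-0.1| + 0.1*(H(.2)+H(.4))/2 = 0.36403 (nats)
        bd, _ = losses.distpu_loss([0.9], [0.2, 0.4], None, 0.1, self.cfg())
        assert bd.total == pytest.approx(0.36403, abs=5e-6)

    def test_mixup_term_recorded(self):
        mixed = (np.array([0.6, 0.4]), np.array([0.5, 0.5]))
        bd, g = losses.distpu_loss([0.9], [0.2], mixed, 0.1, self.cfg())
        assert bd.auxiliary_terms["mixup"] == pytest.approx(0.01, rel=1e-9)
        assert g["mixed"].shape == (2,)


class TestGrab:
    def test_prior_estimator_cap_and_floor(self):
        assert losses.grab_prior([0.6, 0.7, 0.4, 0.3, 0.2]) == 0.05
        assert losses.grab_prior([0.6] + [0.4] * 49, cap=0.05) == 0.02
        assert losses.grab_prior([0.1, 0.2], cap=0.05, floor=0.001) == 0.001

    def _star(self, n_leaves=4):
        return PPINetwork.from_id_edges(
            {("C", f"L{i}"): 900 for i in range(n_leaves)})

    def test_belief_sweep_star_hand_value(self):
        net = self._star(4)
        center = net.index_of("C")
        scores = np.full(5, 0.5)
        beliefs = losses.belief_sweep(scores.copy(), scores, net.adjacency(),
                                      np.array([center]), beta=0.5)
        leaves = [i for i in range(5) if i != center]
        assert np.allclose(beliefs[leaves], 0.75)
        assert beliefs[center] == 1.0

    def test_labeled_positive_pinned_across_sweeps(self):
        net = self._star(4)
        center = net.index_of("C")
        scores = np.full(5, 0.2)
        b = scores.copy()
        for _ in range(5):
            b = losses.belief_sweep(b, scores, net.adjacency(),
                                    np.array([center]), beta=0.5)
            assert b[center] == 1.0

    def test_beta_zero_reduces_to_nnpu_with_dynamic_prior(self):
        from punet.graph import LabelSet
        net = self._star(4)
        center = net.index_of("C")
        labels = LabelSet(frozenset({center}),
                          frozenset(range(5)) - {center})
        scores = np.array([0.4, 0.45, 0.9, 0.35, 0.3])
        scores[center] = 0.9
        cfg = PULossConfig(loss_name="grab", grab_beta=0.0)
        bd, g, beliefs = losses.grab_loss(scores, labels, net, cfg)
        unl = sorted(labels.unlabeled)
        assert np.allclose(beliefs[unl], scores[unl])
        prov = [i for i in unl if scores[i] > 0.5]
        ref, _ = losses.nnpu_loss(scores[[center] + prov], scores[unl],
                                  bd.auxiliary_terms["dynamic_prior"])
        assert bd.total == pytest.approx(ref.total, rel=1e-12)


class TestPugnn:
    def test_zero_lambda_is_nnpu_with_scheduled_prior(self):
        cfg = PULossConfig(loss_name="pugnn", lambda_graph=0.0)
        sp, su = [0.8, 0.7], [0.2, 0.3]
        bd, _ = losses.pugnn_loss(sp, su, None, epoch=50, cfg=cfg)
        ref, _ = losses.nnpu_loss(sp, su, cfg.prior)
        assert bd.total == pytest.approx(ref.total, rel=1e-12)

    def test_equal_scores_zero_smoothness(self):
        cfg = PULossConfig(loss_name="pugnn")
        pairs = np.array([[0.4, 0.4], [0.7, 0.7]])
        bd, _ = losses.pugnn_loss([0.8], [0.4], pairs, epoch=50, cfg=cfg)
        assert bd.auxiliary_terms["smoothness"] == 0.0

    def test_dual_prior_schedule(self):
        cfg = PULossConfig(loss_name="pugnn", warmup_epochs=20)
        bd0, _ = losses.pugnn_loss([0.8], [0.2], None, epoch=0, cfg=cfg)
        bd20, _ = losses.pugnn_loss([0.8], [0.2], None, epoch=20, cfg=cfg)
        assert bd0.auxiliary_terms["prior_used"] == 0.5
        assert bd20.auxiliary_terms["prior_used"] == 0.1


# ---------------------------------------------------------------------------
# Gradient correctness of every loss w.r.t. its score inputs


def _check_grad(fn, arrays, grads, eps=1e-7):
    for arr, g in zip(arrays, grads):
        for idx in np.ndindex(arr.shape):
            old = arr[idx]
            arr[idx] = old + eps
            up = fn()
            arr[idx] = old - eps
            down = fn()
            arr[idx] = old
            num = (up - down) / (2 * eps)
            assert g[idx] == pytest.approx(num, rel=2e-4, abs=1e-7)


def test_generalized_risk_gradient():
    rng = np.random.default_rng(0)
    sp = rng.uniform(0.2, 0.8, 4)
    su = rng.uniform(0.2, 0.8, 6)
    _, g = losses.generalized_pu_risk(sp, su, 0.2)
    _check_grad(lambda: losses.generalized_pu_risk(sp, su, 0.2)[0].total,
                [sp, su], [g["p"], g["u"]])


def test_distpu_gradient_including_mixup():
    rng = np.random.default_rng(1)
    cfg = PULossConfig(loss_name="distpu")
    sp = rng.uniform(0.2, 0.8, 3)
    su = rng.uniform(0.2, 0.8, 5)
    sm = rng.uniform(0.2, 0.8, 4)
    pseudo = rng.uniform(0, 1, 4)
    _, g = losses.distpu_loss(sp, su, (sm, pseudo), 0.1, cfg)
    _check_grad(
        lambda: losses.distpu_loss(sp, su, (sm, pseudo), 0.1, cfg)[0].total,
        [sp, su, sm], [g["p"], g["u"], g["mixed"]])


def test_pugnn_gradient_on_edges():
    cfg = PULossConfig(loss_name="pugnn")
    pairs = np.array([[0.3, 0.6], [0.7, 0.2]])
    _, g = losses.pugnn_loss([0.8], [0.4], pairs, epoch=50, cfg=cfg)
    _check_grad(
        lambda: losses.pugnn_loss([0.8], [0.4], pairs, epoch=50, cfg=cfg)[0].total,
        [pairs], [g["edges"]])
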