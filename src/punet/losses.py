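"""Positive-unlabeled training objectives over (positive, unlabeled) score sets.

All four objectives share the generalized PU risk decomposition

    R_PU(f) = pi_p * E_P[l(f, 1)] + ( E_U[l(f, 0)] - pi_p * E_P[l(f, 0)] )

where ``l`` is pointwise binary cross-entropy on sigmoid scores, ``pi_p`` is
the assumed class prior, and the bracketed term is the surrogate negative
risk estimated from the unlabeled pool and corrected for hidden positives.
The four variants differ in how that surrogate is handled:

* ``nnpu``   — clamps the surrogate negative risk at zero (non-negative
  correction), optionally with the defensive gradient step that descends on
  the negated surrogate when it is clamped.
* ``distpu`` — distribution alignment |E_U[s] - pi_p| plus entropy
  minimization on unlabeled scores and mixup consistency on virtual nodes.
* ``pugnn``  — nnPU plus an edge-smoothness penalty over the interaction
  graph, with a dual prior schedule (warm-up prior, then main prior).
* ``grab``   — belief propagation over the graph refines provisional labels
  and a dynamic prior each epoch; the risk is nnPU on the refined partition.

Every loss returns a :class:`RiskBreakdown` together with the gradient of
the total with respect to the score arrays it was given, so the trainer can
scatter gradients back onto the node-score vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.sparse as sp

__all__ = [
    "PULossConfig",
    "RiskBreakdown",
    "pointwise_loss",
    "generalized_pu_risk",
    "nnpu_loss",
    "distpu_loss",
    "grab_prior",
    "grab_loss",
    "pugnn_loss",
    "LOSS_NAMES",
]

LOSS_NAMES = ("nnpu", "distpu", "pugnn", "grab")


@dataclass(frozen=True)
class PULossConfig:
    """Hyperparameters shared by the four PU objectives.

    ``prior`` is the assumed positive-class fraction pi_p (0.10 by default,
    the conservative estimate used for nnPU and Dist-PU). ``warmup_prior`` /
    ``warmup_epochs`` implement the dual-prior schedule of the graph-
    regularized objective (0.5 for the first 20 epochs, then ``prior``).
    ``grab_cap`` bounds the dynamically estimated prior at 0.05.
    """

    loss_name: str = "nnpu"
    prior: float = 0.10
    warmup_prior: float = 0.5
    # warm-up must not exceed the early-stopping patience (10), or runs
    # stopped at the patience limit never train under the main prior
    warmup_epochs: int = 10
    grab_cap: float = 0.05
    grab_floor: float = 0.001
    grab_beta: float = 0.5
    clip_eps: float = 1e-7
    lambda_graph: float = 0.1
    lambda_entropy: float = 0.1
    lambda_mixup: float = 0.1
    mixup_alpha: float = 1.0
    nnpu_defensive: bool = True

    def __post_init__(self) -> None:
        if self.loss_name not in LOSS_NAMES:
            raise ValueError(f"unknown loss {self.loss_name!r}")
        if not 0 < self.prior < 1:
            raise ValueError("prior must be in (0, 1)")
        if not 0 < self.clip_eps < 0.5:
            raise ValueError("clip_eps must be in (0, 0.5)")
        if self.grab_floor > self.grab_cap:
            raise ValueError("grab_floor must not exceed grab_cap")


@dataclass
class RiskBreakdown:
    """Decomposed value of a PU objective for one evaluation."""

    positive_risk: float
    surrogate_negative_risk: float
    correction_applied: bool
    total: float
    auxiliary_terms: Mapping[str, float] = field(default_factory=dict)


def _clip(p: np.ndarray, eps: float) -> np.ndarray:
    return np.clip(p, eps, 1.0 - eps)


def pointwise_loss(p, y, clip_eps: float = 1e-7):
    """Binary cross-entropy on scores clipped to [eps, 1-eps] (elementwise)."""
    pc = _clip(np.asarray(p, dtype=float), clip_eps)
    y = np.asarray(y, dtype=float)
    return -(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))


def _bce_terms(p: np.ndarray, eps: float):
    """Means and gradients of l(., 1) and l(., 0) over a score array.

    Gradient of the clipped loss is zero outside the clip interval.
    """
    p = np.asarray(p, dtype=float)
    pc = _clip(p, eps)
    inside = (p > eps) & (p < 1.0 - eps)
    n = p.size
    l1 = -np.log(pc)
    l0 = -np.log(1.0 - pc)
    g1 = np.where(inside, -1.0 / pc, 0.0) / n          # d mean l(.,1) / dp
    g0 = np.where(inside, 1.0 / (1.0 - pc), 0.0) / n   # d mean l(.,0) / dp
    return float(l1.mean()), float(l0.mean()), g1, g0


def generalized_pu_risk(scores_p, scores_u, prior: float,
                        clip_eps: float = 1e-7) -> tuple[RiskBreakdown, dict]:
    """Uncorrected PU risk; can go negative when hidden positives dominate."""
    scores_p = np.asarray(scores_p, dtype=float)
    scores_u = np.asarray(scores_u, dtype=float)
    if scores_p.size == 0 or scores_u.size == 0:
        raise ValueError("scores_p and scores_u must be non-empty")
    lp1, lp0, gp1, gp0 = _bce_terms(scores_p, clip_eps)
    lu1, lu0, gu1, gu0 = _bce_terms(scores_u, clip_eps)
    pos = prior * lp1
    neg = lu0 - prior * lp0
    total = pos + neg
    grads = {"p": prior * gp1 - prior * gp0, "u": gu0}
    bd = RiskBreakdown(pos, neg, False, total)
    return bd, grads


def nnpu_loss(scores_p, scores_u, prior: float, clip_eps: float = 1e-7,
              defensive: bool = True) -> tuple[RiskBreakdown, dict]:
    """Non-negative PU risk: total = pos + max(0, surrogate negative risk).

    When the surrogate is negative (a signature of overfitting to hidden
    positives) the reported total drops the negative term; the gradient then
    either vanishes on it (plain clamp) or, in the defensive variant,
    descends on the negated surrogate to push it back above zero.
    """
    scores_p = np.asarray(scores_p, dtype=float)
    scores_u = np.asarray(scores_u, dtype=float)
    if scores_p.size == 0 or scores_u.size == 0:
        raise ValueError("scores_p and scores_u must be non-empty")
    lp1, lp0, gp1, gp0 = _bce_terms(scores_p, clip_eps)
    lu1, lu0, gu1, gu0 = _bce_terms(scores_u, clip_eps)
    pos = prior * lp1
    neg = lu0 - prior * lp0
    clamped = neg < 0
    total = pos + max(0.0, neg)
    if not clamped:
        grads = {"p": prior * gp1 - prior * gp0, "u": gu0}
    elif defensive:
        # descend on -neg = prior*E_P[l(.,0)] - E_U[l(.,0)]
        grads = {"p": prior * gp0, "u": -gu0}
    else:
        grads = {"p": prior * gp1, "u": np.zeros_like(gu0)}
    bd = RiskBreakdown(pos, neg, bool(clamped), total)
    return bd, grads


def _binary_entropy(p: np.ndarray, eps: float):
    pc = _clip(p, eps)
    h = -(pc * np.log(pc) + (1 - pc) * np.log(1 - pc))
    dh = np.log((1 - pc) / pc)
    inside = (p > eps) & (p < 1 - eps)
    return h, np.where(inside, dh, 0.0)


def distpu_loss(scores_p, scores_u, mixed_pairs, prior: float,
                cfg: PULossConfig) -> tuple[RiskBreakdown, dict]:
    """Distribution-aligned PU objective.

    total = E_P[l(.,1)] + |E_U[s] - pi_p| + lambda_entropy * E_U[H(s)]
          + lambda_mixup * E_mix[(s_mix - y_mix)^2]

    ``mixed_pairs`` is ``(mixed_scores, pseudo_labels)`` built by the trainer
    from feature-interpolated virtual nodes (may be ``None``).
    """
    scores_p = np.asarray(scores_p, dtype=float)
    scores_u = np.asarray(scores_u, dtype=float)
    if scores_p.size == 0 or scores_u.size == 0:
        raise ValueError("scores_p and scores_u must be non-empty")
    eps = cfg.clip_eps
    lp1, _, gp1, _ = _bce_terms(scores_p, eps)
    pos = lp1
    grad_p = gp1

    diff = float(scores_u.mean() - prior)
    align = abs(diff)
    grad_u = np.full(scores_u.size, np.sign(diff) / scores_u.size)

    h, dh = _binary_entropy(scores_u, eps)
    ent = float(h.mean())
    grad_u = grad_u + cfg.lambda_entropy * dh / scores_u.size

    aux = {"alignment": align, "entropy": ent}
    grad_mix = None
    mix = 0.0
    if mixed_pairs is not None:
        mixed_scores, pseudo = mixed_pairs
        mixed_scores = np.asarray(mixed_scores, dtype=float)
        pseudo = np.asarray(pseudo, dtype=float)
        resid = mixed_scores - pseudo
        mix = float((resid ** 2).mean())
        grad_mix = cfg.lambda_mixup * 2.0 * resid / resid.size
        aux["mixup"] = mix
    total = pos + align + cfg.lambda_entropy * ent + cfg.lambda_mixup * mix
    bd = RiskBreakdown(pos, align, False, total, aux)
    grads = {"p": grad_p, "u": grad_u, "mixed": grad_mix}
    return bd, grads


def grab_prior(scores_u, cap: float = 0.05, floor: float = 0.001) -> float:
    """Dynamic prior: fraction of unlabeled scores above 0.5, clamped to
    [floor, cap]."""
    scores_u = np.asarray(scores_u, dtype=float)
    if scores_u.size == 0:
        raise ValueError("scores_u must be non-empty")
    frac = float((scores_u > 0.5).mean())
    return float(np.clip(frac, floor, cap))


def belief_sweep(beliefs: np.ndarray, scores: np.ndarray,
                 adjacency: sp.spmatrix, positives: np.ndarray,
                 beta: float) -> np.ndarray:
    """One belief-propagation sweep:

    b_i <- (1 - beta) * s_i + beta * mean_{j in N(i)} b_j,

    with labeled positives pinned at 1 before and after the sweep.
    """
    b = beliefs.copy()
    b[positives] = 1.0
    deg = np.asarray(adjacency.sum(axis=1)).ravel()
    neigh_mean = np.asarray(adjacency @ b).ravel() / np.maximum(deg, 1.0)
    b = (1.0 - beta) * scores + beta * neigh_mean
    b[positives] = 1.0
    return b


def grab_loss(scores_all, labels, net, cfg: PULossConfig,
              belief_state: np.ndarray | None = None
              ) -> tuple[RiskBreakdown, dict, np.ndarray]:
    """Belief-refined PU objective with a dynamically estimated prior.

    One neighbor-averaging sweep refines the belief state (labeled positives
    pinned at 1); unlabeled nodes whose refined belief exceeds 0.5 join the
    positive-side means as provisional positives for this step (the
    unlabeled-side mean is unchanged), the prior is estimated from the
    refined unlabeled beliefs, and the nnPU risk is evaluated on that
    partition. Belief refinement itself carries no gradient.

    Returns (breakdown, grads, new_belief_state); ``grads['all']`` is
    aligned with ``scores_all``.
    """
    scores_all = np.asarray(scores_all, dtype=float)
    pos_idx = np.array(sorted(labels.positives), dtype=int)
    unl_idx = np.array(sorted(labels.unlabeled), dtype=int)
    adjacency = net.adjacency() if hasattr(net, "adjacency") else net
    if belief_state is None:
        belief_state = scores_all.copy()
    beliefs = belief_sweep(belief_state, scores_all, adjacency, pos_idx,
                           cfg.grab_beta)
    prior = grab_prior(beliefs[unl_idx], cfg.grab_cap, cfg.grab_floor)
    provisional = unl_idx[beliefs[unl_idx] > 0.5]
    eff_p = np.concatenate([pos_idx, provisional])
    bd, g = nnpu_loss(scores_all[eff_p], scores_all[unl_idx], prior,
                      cfg.clip_eps, cfg.nnpu_defensive)
    grad_all = np.zeros_like(scores_all)
    grad_all[eff_p] += g["p"]
    grad_all[unl_idx] += g["u"]
    bd.auxiliary_terms = {**bd.auxiliary_terms,
                          "dynamic_prior": prior,
                          "n_provisional": float(provisional.size)}
    return bd, {"all": grad_all}, beliefs


def pugnn_loss(scores_p, scores_u, edge_score_pairs, epoch: int,
               cfg: PULossConfig) -> tuple[RiskBreakdown, dict]:
    """Graph-regularized nnPU with a dual prior schedule.

    total = nnPU(prior_t) + lambda_graph * mean_edges (s_i - s_j)^2, where
    prior_t is ``warmup_prior`` for epochs before ``warmup_epochs`` and the
    main ``prior`` afterwards. ``edge_score_pairs`` is an (E, 2) array of
    scores across every network edge; the returned ``grads['edges']`` has
    the same shape.
    """
    prior = cfg.warmup_prior if epoch < cfg.warmup_epochs else cfg.prior
    bd, g = nnpu_loss(scores_p, scores_u, prior, cfg.clip_eps,
                      cfg.nnpu_defensive)
    grads = {"p": g["p"], "u": g["u"], "edges": None}
    smooth = 0.0
    if edge_score_pairs is not None and len(edge_score_pairs):
        pairs = np.asarray(edge_score_pairs, dtype=float)
        d = pairs[:, 0] - pairs[:, 1]
        smooth = float((d ** 2).mean())
        ge = cfg.lambda_graph * 2.0 * d / d.size
        grads["edges"] = np.stack([ge, -ge], axis=1)
    total = bd.total + cfg.lambda_graph * smooth
    bd2 = RiskBreakdown(bd.positive_risk, bd.surrogate_negative_risk,
                        bd.correction_applied, total,
                        {**bd.auxiliary_terms, "smoothness": smooth,
                         "prior_used": prior})
    return bd2, grads
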