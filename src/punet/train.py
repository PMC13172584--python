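"""Spy-based cross-validation protocol for PU node scoring.

Known positives are split into 5 folds; in each fold 80% train the model
while the remaining 20% ("spies") are silently moved into the unlabeled
pool. Recovery of the spies (score > 0.5) measures sensitivity without any
labeled negatives. Training is full-batch Adam (lr 0.001) for at most 250
epochs with early stopping when spy recall has not improved for 10
consecutive epochs; the parameters of the best spy-recall epoch are kept.

Fold score vectors are combined into a recall-weighted consensus ranking
over the unlabeled candidate pool; rankings from several objectives are
merged by top-k union. Sensitivity sweeps rerun the whole protocol across
a prior grid or a spy-fraction grid.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import gcn, losses
from .graph import FeatureMatrix, LabelSet, PPINetwork

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "FoldResult",
    "ConsensusRanking",
    "CVResult",
    "make_folds",
    "make_spy_splits",
    "train_fold",
    "spy_recall",
    "surrogate_f1",
    "consensus_rank",
    "top_k_union",
    "recall_at_k",
    "run_cv",
    "sensitivity_sweep",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol parameters (Adam lr 0.001, 250 epochs max,
    early-stopping patience 10, recovery threshold 0.5, seed 42)."""

    lr: float = 1e-3
    max_epochs: int = 250
    patience: int = 10
    threshold: float = 0.5
    n_folds: int = 5
    seed: int = 42


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    train_positives: frozenset[int]
    spies: frozenset[int]
    effective_unlabeled: frozenset[int]


@dataclass
class FoldResult:
    scores: np.ndarray          # inference scores at the best-spy-recall epoch
    spy_recall: float
    train_recall: float
    stopped_epoch: int
    history: list[tuple[float, float]]  # (loss total, spy recall) per epoch


@dataclass
class ConsensusRanking:
    """Recall-weighted consensus over folds, restricted to unlabeled nodes,
    ordered by descending score with ties broken by ascending node ID."""

    entries: list[tuple[str, float]]
    weights: tuple[float, ...]

    def top(self, k: int) -> list[str]:
        if len(self.entries) < k:
            raise ValueError(f"ranking has {len(self.entries)} nodes, need {k}")
        return [nid for nid, _ in self.entries[:k]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rank": np.arange(1, len(self.entries) + 1),
             "node": [n for n, _ in self.entries],
             "score": [s for _, s in self.entries]}
        )


def make_folds(labels: LabelSet, k: int = 5, seed: int = 42) -> list[FoldSplit]:
    """Seeded shuffle of the positives, contiguous k-way partition into spy
    sets; each fold's spies are moved into the effective unlabeled pool."""
    positives = np.array(sorted(labels.positives), dtype=int)
    if positives.size < k:
        raise ValueError(f"need at least {k} positives for {k}-fold spy CV")
    rng = np.random.default_rng(seed)
    rng.shuffle(positives)
    folds = []
    for fold_id, spies in enumerate(np.array_split(positives, k)):
        spies_set = frozenset(int(i) for i in spies)
        train_pos = frozenset(labels.positives) - spies_set
        folds.append(FoldSplit(
            fold_id=fold_id,
            train_positives=train_pos,
            spies=spies_set,
            effective_unlabeled=frozenset(labels.unlabeled) | spies_set,
        ))
    return folds


def make_spy_splits(labels: LabelSet, spy_frac: float, seed: int = 42,
                    n_folds: int = 5) -> list[FoldSplit]:
    """Spy splits at an arbitrary spy fraction.

    When ``spy_frac == 1/n_folds`` this is exactly :func:`make_folds` (the
    base protocol); otherwise each fold takes a contiguous chunk of
    ``ceil(spy_frac * |P|)`` positives from the same seeded shuffle, with
    wraparound, so folds remain comparable across fractions.
    """
    if not 0 < spy_frac < 1:
        raise ValueError("spy_frac must be in (0, 1)")
    if abs(spy_frac - 1.0 / n_folds) < 1e-12:
        return make_folds(labels, n_folds, seed)
    positives = np.array(sorted(labels.positives), dtype=int)
    rng = np.random.default_rng(seed)
    rng.shuffle(positives)
    m = int(np.ceil(spy_frac * positives.size))
    folds = []
    for fold_id in range(n_folds):
        start = (fold_id * m) % positives.size
        idx = np.arange(start, start + m) % positives.size
        spies_set = frozenset(int(i) for i in positives[idx])
        folds.append(FoldSplit(
            fold_id=fold_id,
            train_positives=frozenset(labels.positives) - spies_set,
            spies=spies_set,
            effective_unlabeled=frozenset(labels.unlabeled) | spies_set,
        ))
    return folds


def spy_recall(scores: np.ndarray, spies: frozenset[int] | Sequence[int],
               threshold: float = 0.5) -> float:
    """Fraction of spies with score strictly above the threshold (Recall =
    TP / (TP + FN); a spy exactly at the threshold counts as missed)."""
    spies = sorted(spies)
    if not spies:
        raise ValueError("spy set is empty")
    tp = int((scores[np.array(spies)] > threshold).sum())
    return tp / len(spies)


def surrogate_f1(scores: np.ndarray, spies: frozenset[int] | Sequence[int],
                 prior: float, threshold: float = 0.5) -> float:
    """PU surrogate F1: true precision is unobservable, so precision is
    approximated by prior * recall / q with q the fraction of all nodes
    scored above the threshold (clamped to <= 1)."""
    r = spy_recall(scores, spies, threshold)
    if r == 0.0:
        return 0.0
    q = float((scores > threshold).mean())
    if q == 0.0:
        return 0.0
    p_star = min(1.0, prior * r / q)
    return 2.0 * p_star * r / (p_star + r)


# ---------------------------------------------------------------------------
# Fold training


def _mixup_batch(x: np.ndarray, pos_idx: np.ndarray, unl_idx: np.ndarray,
                 alpha: float, rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray, None] | None:
    """Feature-interpolated virtual nodes for the distribution-aligned loss:
    one pair per unlabeled node, lambda ~ Beta(alpha, alpha), pseudo-label =
    lambda-interpolated hard labels (unlabeled treated as 0)."""
    pool = np.concatenate([pos_idx, unl_idx])
    y = np.concatenate([np.ones(pos_idx.size), np.zeros(unl_idx.size)])
    n = unl_idx.size
    ia = rng.integers(0, pool.size, size=n)
    ib = rng.integers(0, pool.size, size=n)
    lam = rng.beta(alpha, alpha, size=n)
    xm = lam[:, None] * x[pool[ia]] + (1 - lam)[:, None] * x[pool[ib]]
    pseudo = lam * y[ia] + (1 - lam) * y[ib]
    return xm, pseudo


def _epoch_loss_and_grad(
    scores: np.ndarray,
    cache,
    params: gcn.ModelParams,
    split: FoldSplit,
    net: PPINetwork,
    x: np.ndarray,
    loss_cfg: losses.PULossConfig,
    epoch: int,
    rng: np.random.Generator,
    state: dict,
    edge_idx: np.ndarray | None,
) -> tuple[losses.RiskBreakdown, gcn.Gradients]:
    """Evaluate the configured PU objective on training-mode scores and
    backpropagate its gradient; returns (breakdown, parameter gradients)."""
    pos_idx = np.array(sorted(split.train_positives), dtype=int)
    unl_idx = np.array(sorted(split.effective_unlabeled), dtype=int)
    name = loss_cfg.loss_name
    d_scores = np.zeros_like(scores)

    if name == "nnpu":
        bd, g = losses.nnpu_loss(scores[pos_idx], scores[unl_idx],
                                 loss_cfg.prior, loss_cfg.clip_eps,
                                 loss_cfg.nnpu_defensive)
        d_scores[pos_idx] += g["p"]
        d_scores[unl_idx] += g["u"]
    elif name == "pugnn":
        pairs = scores[edge_idx] if edge_idx is not None else None
        bd, g = losses.pugnn_loss(scores[pos_idx], scores[unl_idx], pairs,
                                  epoch, loss_cfg)
        d_scores[pos_idx] += g["p"]
        d_scores[unl_idx] += g["u"]
        if g["edges"] is not None:
            np.add.at(d_scores, edge_idx[:, 0], g["edges"][:, 0])
            np.add.at(d_scores, edge_idx[:, 1], g["edges"][:, 1])
    elif name == "grab":
        fold_labels = LabelSet(split.train_positives, split.effective_unlabeled)
        bd, g, state["beliefs"] = losses.grab_loss(
            scores, fold_labels, net, loss_cfg, state.get("beliefs"))
        d_scores += g["all"]
    elif name == "distpu":
        mix = _mixup_batch(x, pos_idx, unl_idx, loss_cfg.mixup_alpha, rng)
        xm, pseudo = mix
        # virtual nodes have no edges: identity aggregation, frozen batch norm
        mixed_scores, mix_cache = gcn.forward(params, None, xm, training=False)
        bd, g = losses.distpu_loss(scores[pos_idx], scores[unl_idx],
                                   (mixed_scores, pseudo), loss_cfg.prior,
                                   loss_cfg)
        d_scores[pos_idx] += g["p"]
        d_scores[unl_idx] += g["u"]
        grads = gcn.backward(params, cache, d_scores)
        mix_grads = gcn.backward(params, mix_cache, g["mixed"])
        for a, b in zip(grads.trainable(), mix_grads.trainable()):
            a += b
        grads.b_out += mix_grads.b_out
        return bd, grads
    else:  # pragma: no cover - guarded by PULossConfig
        raise ValueError(f"unknown loss {name!r}")

    return bd, gcn.backward(params, cache, d_scores)


def train_fold(
    net: PPINetwork,
    x: FeatureMatrix | np.ndarray,
    split: FoldSplit,
    model_cfg: gcn.ModelConfig | None = None,
    loss_cfg: losses.PULossConfig | None = None,
    train_cfg: TrainConfig | None = None,
    a_hat: sp.csr_matrix | None = None,
    use_graph: bool = True,
) -> FoldResult:
    """Train one spy fold end to end and return the best-epoch result.

    ``use_graph=False`` replaces the aggregation operator by the identity
    (the feature-only baseline). A stub objective can be injected by giving
    ``loss_cfg.loss_name`` one of the four known names; protocol tests use
    the public pieces directly.
    """
    model_cfg = model_cfg or gcn.ModelConfig()
    loss_cfg = loss_cfg or losses.PULossConfig()
    train_cfg = train_cfg or TrainConfig()
    xv = x.values if isinstance(x, FeatureMatrix) else np.asarray(x, dtype=float)
    if a_hat is None and use_graph:
        a_hat = gcn.normalized_adjacency(net)
    op = a_hat if use_graph else None

    seed_seq = np.random.SeedSequence([train_cfg.seed, split.fold_id])
    rng = np.random.default_rng(seed_seq)
    params = gcn.init_params(
        gcn.ModelConfig(model_cfg.hidden_dims, model_cfg.dropout_p,
                        seed=model_cfg.seed + split.fold_id),
        xv.shape[1])
    optimizer = gcn.Adam(params, lr=train_cfg.lr)

    edge_idx = None
    if loss_cfg.loss_name == "pugnn" and net.n_edges:
        edge_idx = np.array(sorted(net.edges), dtype=int)

    best = FoldResult(scores=np.full(xv.shape[0], 0.5), spy_recall=-1.0,
                      train_recall=0.0, stopped_epoch=0, history=[])
    state: dict = {}
    stall = 0
    history: list[tuple[float, float]] = []
    pos_idx = np.array(sorted(split.train_positives), dtype=int)

    for epoch in range(1, train_cfg.max_epochs + 1):
        scores, cache = gcn.forward(params, op, xv, training=True, rng=rng,
                                    dropout_p=model_cfg.dropout_p)
        try:
            bd, grads = _epoch_loss_and_grad(
                scores, cache, params, split, net, xv, loss_cfg, epoch - 1,
                rng, state, edge_idx)
        except FloatingPointError as exc:
            raise FloatingPointError(f"non-finite loss at epoch {epoch}") from exc
        if not np.isfinite(bd.total):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        optimizer.step(grads)

        eval_scores, _ = gcn.forward(params, op, xv, training=False)
        r = spy_recall(eval_scores, split.spies, train_cfg.threshold)
        history.append((bd.total, r))
        if r > best.spy_recall:
            best = FoldResult(
                scores=eval_scores,
                spy_recall=r,
                train_recall=spy_recall(eval_scores, pos_idx, train_cfg.threshold),
                stopped_epoch=epoch,
                history=history,
            )
            stall = 0
        else:
            stall += 1
            if stall >= train_cfg.patience:
                best.stopped_epoch = epoch
                break
    best.history = history
    best.stopped_epoch = len(history)
    return best


# ---------------------------------------------------------------------------
# Ranking and aggregation


def consensus_rank(fold_results: Sequence[FoldResult], labels: LabelSet,
                   node_ids: Sequence[str]) -> ConsensusRanking:
    """Recall-weighted average of fold score vectors over the unlabeled
    candidate pool: consensus_i = sum_f r_f s_{i,f} / sum_f r_f."""
    weights = np.array([max(fr.spy_recall, 0.0) for fr in fold_results])
    if weights.sum() <= 0:
        raise ValueError("no informative folds (all fold recalls are zero)")
    stacked = np.stack([fr.scores for fr in fold_results])
    consensus = weights @ stacked / weights.sum()
    unl = sorted(labels.unlabeled)
    entries = sorted(((node_ids[i], float(consensus[i])) for i in unl),
                     key=lambda t: (-t[1], t[0]))
    return ConsensusRanking(entries, tuple(float(w) for w in weights))


def top_k_union(rankings: Mapping[str, ConsensusRanking], k: int = 100
                ) -> tuple[set[str], dict[str, set[str]]]:
    """Union of each model's top-k plus, per node, the set of models that
    voted for it (enables the 'predicted by all models' report)."""
    union: set[str] = set()
    votes: dict[str, set[str]] = {}
    for model, ranking in rankings.items():
        for nid in ranking.top(k):
            union.add(nid)
            votes.setdefault(nid, set()).add(model)
    return union, votes


def recall_at_k(ranking: ConsensusRanking, target_set: set[str], k: int) -> float:
    """Fraction of the target set appearing in the ranking's top k."""
    if not target_set:
        raise ValueError("target set is empty")
    top = set(ranking.top(min(k, len(ranking.entries))))
    return len(top & target_set) / len(target_set)


@dataclass
class CVResult:
    fold_results: list[FoldResult]
    consensus: ConsensusRanking
    loss_cfg: losses.PULossConfig

    @property
    def mean_spy_recall(self) -> float:
        return float(np.mean([f.spy_recall for f in self.fold_results]))

    @property
    def sd_spy_recall(self) -> float:
        return float(np.std([f.spy_recall for f in self.fold_results]))

    def metrics(self) -> dict:
        return {
            "loss": self.loss_cfg.loss_name,
            "mean_spy_recall": self.mean_spy_recall,
            "sd_spy_recall": self.sd_spy_recall,
            "fold_spy_recall": [f.spy_recall for f in self.fold_results],
            "fold_train_recall": [f.train_recall for f in self.fold_results],
            "fold_stopped_epoch": [f.stopped_epoch for f in self.fold_results],
        }


def run_cv(
    net: PPINetwork,
    x: FeatureMatrix | np.ndarray,
    labels: LabelSet,
    model_cfg: gcn.ModelConfig | None = None,
    loss_cfg: losses.PULossConfig | None = None,
    train_cfg: TrainConfig | None = None,
    folds: Sequence[FoldSplit] | None = None,
    use_graph: bool = True,
) -> CVResult:
    """Full spy cross-validation for one objective: train every fold, then
    build the recall-weighted consensus ranking over the unlabeled pool."""
    model_cfg = model_cfg or gcn.ModelConfig()
    loss_cfg = loss_cfg or losses.PULossConfig()
    train_cfg = train_cfg or TrainConfig()
    if folds is None:
        folds = make_folds(labels, train_cfg.n_folds, train_cfg.seed)
    a_hat = gcn.normalized_adjacency(net) if use_graph else None
    results = [
        train_fold(net, x, split, model_cfg, loss_cfg, train_cfg,
                   a_hat=a_hat, use_graph=use_graph)
        for split in folds
    ]
    consensus = consensus_rank(results, labels, net.node_ids)
    return CVResult(results, consensus, loss_cfg)


def _fingerprint(ids: set[str]) -> str:
    return hashlib.sha256("\n".join(sorted(ids)).encode()).hexdigest()[:16]


def sensitivity_sweep(
    axis: str,
    grid: Sequence[float],
    net: PPINetwork,
    x: FeatureMatrix | np.ndarray,
    labels: LabelSet,
    model_cfg: gcn.ModelConfig | None = None,
    loss_cfg: losses.PULossConfig | None = None,
    train_cfg: TrainConfig | None = None,
    top_k: int = 100,
) -> pd.DataFrame:
    """Rerun the full CV across a prior or spy-fraction grid.

    Returns one row per grid point: setting, mean/sd spy recall, and a
    fingerprint (hash) of the sorted top-k set, which makes stability of the
    candidate list across settings directly comparable.
    """
    if axis not in ("prior", "spy_fraction"):
        raise ValueError("axis must be 'prior' or 'spy_fraction'")
    model_cfg = model_cfg or gcn.ModelConfig()
    loss_cfg = loss_cfg or losses.PULossConfig()
    train_cfg = train_cfg or TrainConfig()
    rows = []
    for setting in grid:
        cfg = loss_cfg
        folds = None
        if axis == "prior":
            cfg = replace(loss_cfg, prior=float(setting))
        else:
            folds = make_spy_splits(labels, float(setting), train_cfg.seed,
                                    train_cfg.n_folds)
        res = run_cv(net, x, labels, model_cfg, cfg, train_cfg, folds=folds)
        k = min(top_k, len(res.consensus.entries))
        rows.append({
            "axis": axis,
            "setting": float(setting),
            "mean_recall": res.mean_spy_recall,
            "sd_recall": res.sd_spy_recall,
            "union_fingerprint": _fingerprint(set(res.consensus.top(k))),
        })
    return pd.DataFrame(rows)
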