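"""Non-PU comparators: random walk with restart, feature-only scorer, and
graph-only (topology-feature) scorer.

The two trained baselines reuse the spy cross-validation protocol verbatim
and differ only in their inputs: the feature-only model drops the graph
(identity aggregation, a multilayer perceptron in effect), the graph-only
model drops the molecular features (replaced by four z-scored topology
descriptors). RWR is training-free network propagation from the labeled
positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp

from . import gcn, losses, train
from .graph import FeatureMatrix, LabelSet, PPINetwork

logger = logging.getLogger(__name__)

__all__ = [
    "RWRConfig",
    "rwr_scores",
    "rwr_ranking",
    "feature_only_scores",
    "graph_only_scores",
    "topology_features",
]


@dataclass(frozen=True)
class RWRConfig:
    """Random-walk-with-restart parameters (classic defaults: restart 0.15)."""

    restart_prob: float = 0.15
    tol: float = 1e-8
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.restart_prob <= 1:
            raise ValueError("restart_prob must be in (0, 1]")


def rwr_scores(net: PPINetwork, seeds: frozenset[int] | set[int],
               cfg: RWRConfig | None = None) -> np.ndarray:
    """Stationary visiting probabilities of a restart walk from the seeds.

    Iterates p <- c e + (1 - c) W^T p with e uniform over seeds and W the
    column-normalized adjacency, until the L1 change drops below tol. The
    result sums to 1 and is the propagation proximity of every node to the
    seed set.
    """
    cfg = cfg or RWRConfig()
    if not seeds:
        raise ValueError("seed set is empty")
    n = net.n_nodes
    if any(s < 0 or s >= n for s in seeds):
        raise ValueError("seed index outside the graph")
    a = net.adjacency().astype(float)
    col_sums = np.asarray(a.sum(axis=0)).ravel()
    w = a @ sp.diags(1.0 / np.maximum(col_sums, 1.0))  # column-stochastic
    e = np.zeros(n)
    e[sorted(seeds)] = 1.0 / len(seeds)
    p = e.copy()
    c = cfg.restart_prob
    for _ in range(cfg.max_iter):
        p_next = c * e + (1.0 - c) * (w @ p)
        if np.abs(p_next - p).sum() < cfg.tol:
            return p_next
        p = p_next
    logger.warning("RWR did not converge within %d iterations", cfg.max_iter)
    return p


def rwr_ranking(net: PPINetwork, labels: LabelSet,
                cfg: RWRConfig | None = None) -> train.ConsensusRanking:
    """RWR seeded on the labeled positives, ranked over the unlabeled pool."""
    p = rwr_scores(net, set(labels.positives), cfg)
    entries = sorted(((net.node_ids[i], float(p[i])) for i in sorted(labels.unlabeled)),
                     key=lambda t: (-t[1], t[0]))
    return train.ConsensusRanking(entries, (1.0,))


def feature_only_scores(
    x: FeatureMatrix | np.ndarray,
    labels: LabelSet,
    net: PPINetwork,
    model_cfg: gcn.ModelConfig | None = None,
    loss_cfg: losses.PULossConfig | None = None,
    train_cfg: train.TrainConfig | None = None,
) -> train.CVResult:
    """Same protocol and nnPU objective, identity in place of the graph
    operator: an MLP on the frozen molecular features."""
    loss_cfg = loss_cfg or losses.PULossConfig(loss_name="nnpu")
    return train.run_cv(net, x, labels, model_cfg, loss_cfg, train_cfg,
                        use_graph=False)


def topology_features(net: PPINetwork) -> np.ndarray:
    """Four z-scored per-node topology descriptors: degree, clustering
    coefficient, core number, mean neighbor degree."""
    g = net.to_networkx()
    order = net.node_ids
    deg = dict(g.degree())
    clust = nx.clustering(g)
    core = nx.core_number(g)
    nbr = nx.average_neighbor_degree(g)
    cols = [
        np.array([deg[n] for n in order], dtype=float),
        np.array([clust[n] for n in order], dtype=float),
        np.array([core[n] for n in order], dtype=float),
        np.array([nbr[n] for n in order], dtype=float),
    ]
    x = np.stack(cols, axis=1)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    return (x - mu) / np.where(sd > 0, sd, 1.0)


def graph_only_scores(
    net: PPINetwork,
    labels: LabelSet,
    model_cfg: gcn.ModelConfig | None = None,
    loss_cfg: losses.PULossConfig | None = None,
    train_cfg: train.TrainConfig | None = None,
) -> train.CVResult:
    """Same protocol and nnPU objective, molecular features replaced by the
    four topology descriptors (graph signal only)."""
    loss_cfg = loss_cfg or losses.PULossConfig(loss_name="nnpu")
    x = topology_features(net)
    return train.run_cv(net, x, labels, model_cfg, loss_cfg, train_cfg,
                        use_graph=True)
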