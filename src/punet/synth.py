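"""Synthetic benchmark instances with a planted disease module.

Emulates the structure the prioritization pipeline sees on real data:
a connected scale-free-like interaction network (preferential attachment,
mimicking PPI degree heterogeneity), a cohesive planted module of true
disease proteins (extra intra-module edges), node features whose mean is
shifted on informative columns for true positives, SCAR-style partial
labeling of the positive set, and per-category annotation gene sets with
one signal term covering the planted module.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .graph import AnnotationSets, FeatureMatrix, LabelSet, PPINetwork, write_edge_list, write_gmt

__all__ = [
    "SynthConfig",
    "generate_network",
    "generate_features",
    "label_scar",
    "generate_annotations",
    "generate_instance",
    "write_instance",
    "SynthInstance",
]

#: Annotation category names mirroring the real pipeline's five categories.
CATEGORIES = ("tissue", "go_bp", "go_mf", "go_cc", "pathway")

# Real-data background-count cap is 500 of 8,300 proteins; synthetic term
# sizes are scaled by the same fraction of the node count.
_BG_CAP_FRACTION = 500 / 8300


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study conditions.

    Defaults give a desk-scale instance: a 2,000-node preferential-attachment
    graph (3 edges per new node), a 60-node planted module densified with
    extra internal edges, 64 features of which 16 carry a +1.0 mean shift for
    true positives, and 60% of true positives labeled (SCAR).
    """

    n_nodes: int = 2000
    attach_m: int = 3
    module_size: int = 60
    rewire_into_module: float = 1.0
    n_features: int = 64
    n_informative: int = 16
    effect_size: float = 1.0
    label_frac: float = 0.6
    n_terms_per_category: int = 8
    seed: int = 42

    def __post_init__(self) -> None:
        if not self.module_size < self.n_nodes:
            raise ValueError("module_size must be smaller than n_nodes")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if self.attach_m < 1:
            raise ValueError("attach_m must be at least 1")
        if not 0 < self.label_frac <= 1:
            raise ValueError("label_frac must be in (0, 1]")
        if not 0 <= self.rewire_into_module <= 1:
            raise ValueError("rewire_into_module must be in [0, 1]")


def _node_id(i: int, n: int) -> str:
    width = len(str(n - 1))
    return f"P{i:0{width}d}"


def _module_indices(cfg: SynthConfig) -> np.ndarray:
    """Planted-module node indices: a seeded uniform sample of the node set."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    return np.sort(rng.choice(cfg.n_nodes, size=cfg.module_size, replace=False))


def generate_network(cfg: SynthConfig) -> PPINetwork:
    """Connected preferential-attachment graph with a densified planted module.

    On top of the Barabási–Albert backbone, ``ceil(rewire_into_module *
    module_size)`` extra edges are sampled uniformly among module node pairs
    (duplicates skipped), so the module is denser than background whenever
    ``rewire_into_module > 0``.
    """
    g = nx.barabasi_albert_graph(cfg.n_nodes, cfg.attach_m, seed=cfg.seed)
    module = _module_indices(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n_extra = int(np.ceil(cfg.rewire_into_module * cfg.module_size))
    added = 0
    while added < n_extra:
        i, j = rng.choice(module, size=2, replace=False)
        if not g.has_edge(i, j):
            g.add_edge(i, j)
            added += 1
    id_edges = {
        (_node_id(a, cfg.n_nodes), _node_id(b, cfg.n_nodes)): 900.0
        for a, b in g.edges()
    }
    return PPINetwork.from_id_edges(id_edges)


def true_positive_ids(cfg: SynthConfig) -> frozenset[str]:
    return frozenset(_node_id(i, cfg.n_nodes) for i in _module_indices(cfg))


def generate_features(net: PPINetwork, cfg: SynthConfig) -> tuple[FeatureMatrix, frozenset[int]]:
    """Standard-normal features; informative columns of true positives are
    shifted by ``effect_size``. Returns the matrix and the true-positive
    index set (the planted module, in network index space)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    x = rng.standard_normal((net.n_nodes, cfg.n_features))
    tp_ids = true_positive_ids(cfg)
    tp_idx = frozenset(i for i, n in enumerate(net.node_ids) if n in tp_ids)
    rows = sorted(tp_idx)
    x[np.ix_(rows, range(cfg.n_informative))] += cfg.effect_size
    return FeatureMatrix(x), tp_idx


def label_scar(true_positives: frozenset[int], n_nodes: int,
               label_frac: float, seed: int) -> LabelSet:
    """SCAR labeling: a seeded uniform shuffle of the true positives, keeping
    ``ceil(label_frac * |TP|)`` of them as labeled; the rest join the
    unlabeled pool with all background nodes."""
    if not 0 < label_frac <= 1:
        raise ValueError("label_frac must be in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    tp = np.array(sorted(true_positives))
    rng.shuffle(tp)
    n_label = int(np.ceil(label_frac * len(tp)))
    if n_label == 0:
        raise ValueError("labeling produced an empty positive set")
    pos = frozenset(int(i) for i in tp[:n_label])
    unl = frozenset(range(n_nodes)) - pos
    return LabelSet(pos, unl)


def generate_annotations(net: PPINetwork, true_positives: frozenset[int],
                         cfg: SynthConfig) -> AnnotationSets:
    """Per category: one signal term = planted module plus noise members,
    the remaining terms random node subsets with sizes straddling the
    scaled background-count cap."""
    bg_cap = max(10, int(round(_BG_CAP_FRACTION * net.n_nodes)))
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 5]))
    all_ids = np.array(net.node_ids)
    tp_ids = sorted(net.node_ids[i] for i in true_positives)
    categories: dict[str, dict[str, frozenset[str]]] = {}
    names: dict[str, str] = {}
    for ci, cat in enumerate(CATEGORIES):
        terms: dict[str, frozenset[str]] = {}
        sig = f"{cat.upper()}:SIGNAL"
        n_noise = int(rng.integers(5, max(6, bg_cap - len(tp_ids))))
        noise = rng.choice(all_ids, size=n_noise, replace=False)
        terms[sig] = frozenset(tp_ids) | frozenset(map(str, noise))
        names[sig] = f"{cat} signal term (planted module)"
        for t in range(cfg.n_terms_per_category - 1):
            term = f"{cat.upper()}:{t:04d}"
            # half the random terms stay under the cap, half exceed it
            if t % 2 == 0:
                size = int(rng.integers(5, bg_cap + 1))
            else:
                size = int(rng.integers(bg_cap + 1, max(bg_cap + 2, 2 * bg_cap)))
            size = min(size, net.n_nodes)
            members = rng.choice(all_ids, size=size, replace=False)
            terms[term] = frozenset(map(str, members))
            names[term] = f"{cat} random term {t}"
        categories[cat] = terms
    return AnnotationSets(categories, names)


@dataclass(frozen=True)
class SynthInstance:
    """A complete synthetic study: network, features, labels, truth, annotations."""

    config: SynthConfig
    network: PPINetwork
    features: FeatureMatrix
    true_positives: frozenset[int]
    labels: LabelSet
    annotations: AnnotationSets

    @property
    def held_out_positives(self) -> frozenset[int]:
        """True positives whose labels were withheld by SCAR labeling."""
        return self.true_positives - self.labels.positives


def generate_instance(cfg: SynthConfig) -> SynthInstance:
    net = generate_network(cfg)
    feats, tp = generate_features(net, cfg)
    labels = label_scar(tp, net.n_nodes, cfg.label_frac, cfg.seed)
    ann = generate_annotations(net, tp, cfg)
    return SynthInstance(cfg, net, feats, tp, labels, ann)


def write_instance(inst: SynthInstance, outdir: str | Path) -> dict[str, Path]:
    """Write the instance as the plain-text files the loaders read back:
    edges.tsv, features.tsv, labels.txt, truth.txt, <category>.gmt, config.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["edges"] = outdir / "edges.tsv"
    write_edge_list(inst.network, paths["edges"])

    paths["features"] = outdir / "features.tsv"
    cols = "\t".join(f"f{j}" for j in range(inst.features.n_features))
    with open(paths["features"], "w") as fh:
        fh.write(f"protein\t{cols}\n")
        for i, node in enumerate(inst.network.node_ids):
            row = "\t".join(f"{v:.8g}" for v in inst.features.values[i])
            fh.write(f"{node}\t{row}\n")

    paths["labels"] = outdir / "labels.txt"
    with open(paths["labels"], "w") as fh:
        for i in sorted(inst.labels.positives):
            fh.write(inst.network.node_ids[i] + "\n")

    paths["truth"] = outdir / "truth.txt"
    with open(paths["truth"], "w") as fh:
        for i in sorted(inst.true_positives):
            fh.write(inst.network.node_ids[i] + "\n")

    for cat, terms in inst.annotations.categories.items():
        p = outdir / f"{cat}.gmt"
        write_gmt(terms, p, inst.annotations.term_names)
        paths[f"gmt:{cat}"] = p

    paths["config"] = outdir / "config.json"
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(inst.config), fh, indent=2)
    return paths
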