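"""End-to-end orchestration: data loading, multi-objective training,
consensus ranking, union, enrichment refinement, and topology profiling.

Every stage writes its artifact (plain TSV/JSON, seed recorded in the
header) before the next stage begins, so any stage can be audited or rerun
on the previous stage's files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import baselines, enrich, gcn, losses, topo, train
from .graph import (AnnotationSets, FeatureMatrix, LabelSet, PPINetwork,
                    align_features, largest_connected_component,
                    make_label_set, read_edge_list, read_feature_table,
                    read_gmt, read_labels)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_inputs", "run_models", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Run-level configuration assembled from a YAML file and CLI flags."""

    seed: int = 42
    min_confidence: float = 700
    top_k: int = 100
    threshold: float = 0.5
    loss_names: tuple[str, ...] = losses.LOSS_NAMES
    hidden_dims: tuple[int, int, int] = (256, 64, 16)
    dropout_p: float = 0.5
    prior: float = 0.10
    max_epochs: int = 250
    patience: int = 10
    n_folds: int = 5

    def model_cfg(self) -> gcn.ModelConfig:
        return gcn.ModelConfig(self.hidden_dims, self.dropout_p, self.seed)

    def loss_cfg(self, name: str) -> losses.PULossConfig:
        return losses.PULossConfig(loss_name=name, prior=self.prior)

    def train_cfg(self) -> train.TrainConfig:
        return train.TrainConfig(max_epochs=self.max_epochs,
                                 patience=self.patience,
                                 threshold=self.threshold,
                                 n_folds=self.n_folds, seed=self.seed)

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "RunConfig":
        kw = {}
        model = cfg.get("model", {})
        loss = cfg.get("loss", {})
        tr = cfg.get("train", {})
        ev = cfg.get("eval", {})
        if "seed" in cfg:
            kw["seed"] = int(cfg["seed"])
        if "min_confidence" in cfg.get("data", {}):
            kw["min_confidence"] = float(cfg["data"]["min_confidence"])
        if "hidden_dims" in model:
            kw["hidden_dims"] = tuple(model["hidden_dims"])
        if "dropout_p" in model:
            kw["dropout_p"] = float(model["dropout_p"])
        if "names" in loss:
            kw["loss_names"] = tuple(loss["names"])
        if "prior" in loss:
            kw["prior"] = float(loss["prior"])
        if "max_epochs" in tr:
            kw["max_epochs"] = int(tr["max_epochs"])
        if "patience" in tr:
            kw["patience"] = int(tr["patience"])
        if "n_folds" in tr:
            kw["n_folds"] = int(tr["n_folds"])
        if "top_k" in ev:
            kw["top_k"] = int(ev["top_k"])
        if "threshold" in ev:
            kw["threshold"] = float(ev["threshold"])
        return cls(**kw)


def load_inputs(data_cfg: Mapping, min_confidence: float = 700
                ) -> tuple[PPINetwork, FeatureMatrix, LabelSet, AnnotationSets | None]:
    """Read edges/features/labels/annotations per the data config block.

    The network is confidence-filtered and reduced to its largest connected
    component before features and labels are aligned to it.
    """
    for key in ("edges", "features", "labels"):
        if key not in data_cfg:
            raise FileNotFoundError(f"data config is missing {key!r}")
        if not Path(data_cfg[key]).exists():
            raise FileNotFoundError(f"input file not found: {data_cfg[key]}")
    net = read_edge_list(data_cfg["edges"], min_confidence)
    net = largest_connected_component(net)
    feats = align_features(net, read_feature_table(data_cfg["features"]))
    labels = make_label_set(net, read_labels(data_cfg["labels"]))
    ann = None
    if data_cfg.get("annotations"):
        ann = read_gmt(data_cfg["annotations"])
    return net, feats, labels, ann


def _write_tsv(df: pd.DataFrame, path: Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed: {seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def run_models(
    net: PPINetwork,
    feats: FeatureMatrix | np.ndarray,
    labels: LabelSet,
    cfg: RunConfig,
    outdir: Path | None = None,
) -> dict[str, train.CVResult]:
    """Spy CV for every configured objective; optionally write per-model
    history and consensus artifacts as each finishes."""
    results: dict[str, train.CVResult] = {}
    folds = train.make_folds(labels, cfg.n_folds, cfg.seed)
    a_model = cfg.model_cfg()
    t_cfg = cfg.train_cfg()
    for name in cfg.loss_names:
        logger.info("training objective %s (%d folds)", name, len(folds))
        res = train.run_cv(net, feats, labels, a_model, cfg.loss_cfg(name),
                           t_cfg, folds=folds)
        results[name] = res
        if outdir is not None:
            hist = pd.DataFrame(
                [(fi, e + 1, l, r)
                 for fi, fr in enumerate(res.fold_results)
                 for e, (l, r) in enumerate(fr.history)],
                columns=["fold", "epoch", "loss_total", "spy_recall"],
            )
            _write_tsv(hist, outdir / f"history_{name}.tsv", cfg.seed)
            _write_tsv(res.consensus.to_frame(),
                       outdir / f"consensus_{name}.tsv", cfg.seed)
            with open(outdir / f"metrics_{name}.json", "w") as fh:
                json.dump({"seed": cfg.seed, **res.metrics()}, fh, indent=2)
    return results


def run_pipeline(
    net: PPINetwork,
    feats: FeatureMatrix | np.ndarray,
    labels: LabelSet,
    annotations: AnnotationSets | None,
    cfg: RunConfig,
    outdir: str | Path,
) -> dict:
    """The full prioritization flow.

    For each configured PU objective: 5-fold spy CV and recall-weighted
    consensus ranking; then the top-k union with per-model votes, the
    enrichment-based intersection refinement (when annotations are given),
    and the topology report on the refined candidates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = run_models(net, feats, labels, cfg, outdir)

    union, votes = train.top_k_union(
        {n: r.consensus for n, r in results.items()}, cfg.top_k)
    union_df = pd.DataFrame(
        [{"node": nid,
          **{name: name in votes[nid] for name in cfg.loss_names},
          "n_models": len(votes[nid])}
         for nid in sorted(union)]
    )
    _write_tsv(union_df, outdir / "union.tsv", cfg.seed)

    refined: set[str] = set()
    if annotations is not None:
        background = set(net.node_ids)
        table = enrich.enrich_all(union, annotations, background)
        if not table.empty:
            _write_tsv(table, outdir / "enrichment.tsv", cfg.seed)
        refined, coverage = enrich.refine_candidates(union, table, annotations)
        refined_df = pd.DataFrame({"node": sorted(refined)})
        _write_tsv(refined_df, outdir / "refined_candidates.tsv", cfg.seed)
        if not coverage.empty:
            _write_tsv(coverage, outdir / "coverage.tsv", cfg.seed)
        if not refined:
            logger.warning("no candidates survived enrichment refinement")

    report_nodes = sorted(refined) if refined else sorted(union)
    topo_df = topo.topology_report(net, labels, report_nodes)
    _write_tsv(topo_df, outdir / "topology.tsv", cfg.seed)

    summary = {
        "seed": cfg.seed,
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "n_positives": len(labels.positives),
        "n_unlabeled": len(labels.unlabeled),
        "union_size": len(union),
        "n_refined": len(refined),
        "models": {n: r.metrics() for n, r in results.items()},
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return {"results": results, "union": union, "votes": votes,
            "refined": refined, "summary": summary}
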