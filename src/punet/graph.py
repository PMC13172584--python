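"""Protein-protein interaction network I/O and canonical indexing.

Reads STRING-style weighted edge lists, node feature tables, positive-label
lists and GMT annotation files, and fixes the canonical node ordering
(lexicographically sorted protein IDs) that every downstream module relies on.
Edge confidence scores are kept as metadata; message passing and topology
metrics operate on the unweighted simple graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "PPINetwork",
    "FeatureMatrix",
    "LabelSet",
    "AnnotationSets",
    "load_network",
    "read_edge_list",
    "write_edge_list",
    "largest_connected_component",
    "align_features",
    "read_feature_table",
    "read_labels",
    "make_label_set",
    "read_gmt",
    "write_gmt",
    "apply_id_mapping",
]


class NetworkError(ValueError):
    """Raised for malformed or empty network inputs."""


@dataclass(frozen=True)
class PPINetwork:
    """Undirected simple graph over protein IDs with edge confidence metadata.

    ``node_ids`` is lexicographically sorted and defines the index space used
    by every aligned artifact (feature rows, score vectors, label sets).
    Edges are stored as index pairs ``(i, j)`` with ``i < j``; ``weights``
    maps each edge to its confidence score as read (0-1000 scale, unchanged).
    """

    node_ids: tuple[str, ...]
    edges: frozenset[tuple[int, int]]
    weights: Mapping[tuple[int, int], float] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, node_id: str) -> int:
        return self._index()[node_id]

    def _index(self) -> dict[str, int]:
        # cached lazily on the instance despite frozen dataclass
        idx = self.__dict__.get("_idx")
        if idx is None:
            idx = {n: i for i, n in enumerate(self.node_ids)}
            object.__setattr__(self, "_idx", idx)
        return idx

    def adjacency(self) -> sp.csr_matrix:
        """Unweighted symmetric adjacency in canonical node order."""
        n = self.n_nodes
        if not self.edges:
            return sp.csr_matrix((n, n))
        ij = np.array(sorted(self.edges), dtype=np.int64)
        rows = np.concatenate([ij[:, 0], ij[:, 1]])
        cols = np.concatenate([ij[:, 1], ij[:, 0]])
        data = np.ones(rows.shape[0])
        return sp.csr_matrix((data, (rows, cols)), shape=(n, n))

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=1)).ravel().astype(np.int64)

    def neighbors(self, i: int) -> np.ndarray:
        a = self.adjacency()
        return a.indices[a.indptr[i]:a.indptr[i + 1]]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        for (i, j) in self.edges:
            g.add_edge(self.node_ids[i], self.node_ids[j],
                       weight=self.weights.get((i, j), 1.0))
        return g

    @classmethod
    def from_id_edges(cls, id_edges: Mapping[tuple[str, str], float]) -> "PPINetwork":
        """Build from a mapping {(idA, idB): weight}; IDs define the node set."""
        nodes = sorted({n for pair in id_edges for n in pair})
        idx = {n: i for i, n in enumerate(nodes)}
        edges = {}
        for (a, b), w in id_edges.items():
            i, j = idx[a], idx[b]
            if i == j:
                continue
            key = (i, j) if i < j else (j, i)
            if key not in edges or w > edges[key]:
                edges[key] = w
        return cls(tuple(nodes), frozenset(edges), dict(edges))


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-node numeric vectors, row-aligned to a network's node order."""

    values: np.ndarray  # shape (n_nodes, n_features)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise NetworkError("feature matrix must be 2-dimensional")
        if not np.all(np.isfinite(v)):
            raise NetworkError("feature matrix contains missing/non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class LabelSet:
    """Partition of node indices into labeled positives and unlabeled."""

    positives: frozenset[int]
    unlabeled: frozenset[int]

    def __post_init__(self) -> None:
        if self.positives & self.unlabeled:
            raise NetworkError("positives and unlabeled overlap")
        if len(self.positives) < 1:
            raise NetworkError("at least one labeled positive is required")

    @property
    def n_nodes(self) -> int:
        return len(self.positives) + len(self.unlabeled)


@dataclass(frozen=True)
class AnnotationSets:
    """Gene-set annotations grouped by category (tissue / GO / pathway)."""

    categories: Mapping[str, Mapping[str, frozenset[str]]]
    term_names: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cat, terms in self.categories.items():
            for term, members in terms.items():
                if not members:
                    raise NetworkError(f"term {term!r} in category {cat!r} is empty")


# ---------------------------------------------------------------------------
# Network construction


def load_network(
    edge_records: Iterable[tuple[str, str, float]],
    min_confidence: float = 700,
) -> PPINetwork:
    """Build a PPI network from (idA, idB, score) rows.

    Edges with confidence strictly greater than ``min_confidence`` are kept
    (the conventional high-confidence STRING cut is 700 on the 0-1000 scale).
    Self-loops are dropped; duplicate edges collapse to their maximum score.
    Node IDs are the sorted unique endpoints of the surviving edges.
    """
    kept: dict[tuple[str, str], float] = {}
    for rownum, rec in enumerate(edge_records, start=1):
        try:
            a, b, raw = rec
            score = float(raw)
        except (TypeError, ValueError) as exc:
            raise NetworkError(f"malformed edge row {rownum}: {rec!r}") from exc
        if a == b:
            continue
        if score <= min_confidence:
            continue
        key = (a, b) if a < b else (b, a)
        if key not in kept or score > kept[key]:
            kept[key] = score
    if not kept:
        raise NetworkError("no edges above threshold")
    return PPINetwork.from_id_edges(kept)


def read_edge_list(path: str | Path, min_confidence: float = 700) -> PPINetwork:
    """Read a 3-column TSV (protein1, protein2, combined_score).

    Lines starting with '#' are ignored; a header row whose third column is
    not numeric is ignored as well.
    """
    records: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise NetworkError(f"malformed edge line: {line!r}")
            try:
                score = float(parts[2])
            except ValueError:
                if not records:  # tolerate a single header line
                    continue
                raise NetworkError(f"malformed edge line: {line!r}")
            records.append((parts[0], parts[1], score))
    return load_network(records, min_confidence)


def write_edge_list(net: PPINetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#protein1\tprotein2\tcombined_score\n")
        for (i, j) in sorted(net.edges):
            w = net.weights.get((i, j), 1.0)
            wtxt = f"{int(w)}" if float(w).is_integer() else f"{w}"
            fh.write(f"{net.node_ids[i]}\t{net.node_ids[j]}\t{wtxt}\n")


def largest_connected_component(net: PPINetwork) -> PPINetwork:
    """Induced subgraph on the largest connected component.

    Ties on component size are broken toward the component containing the
    lexicographically smallest node ID, so the result is deterministic.
    """
    if net.n_nodes == 0:
        raise NetworkError("empty network")
    n = net.n_nodes
    n_comp, labels = sp.csgraph.connected_components(net.adjacency(), directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    best = max(
        range(n_comp),
        key=lambda c: (sizes[c], -min(i for i in range(n) if labels[i] == c)),
    )
    keep = {i for i in range(n) if labels[i] == best}
    id_edges = {
        (net.node_ids[i], net.node_ids[j]): net.weights.get((i, j), 1.0)
        for (i, j) in net.edges
        if i in keep and j in keep
    }
    if not id_edges:
        # single-node component: a graph with no edges
        node = min(net.node_ids[i] for i in keep)
        return PPINetwork((node,), frozenset(), {})
    return PPINetwork.from_id_edges(id_edges)


# ---------------------------------------------------------------------------
# Feature / label / annotation plumbing


def align_features(net: PPINetwork, table: pd.DataFrame) -> FeatureMatrix:
    """Reorder a protein-keyed numeric table to the network's node order.

    ``table`` is indexed by protein ID. Rows for proteins outside the network
    are dropped (a count is logged); a missing row for any network node is
    fatal.
    """
    missing = [n for n in net.node_ids if n not in table.index]
    if missing:
        shown = ", ".join(missing[:10])
        raise NetworkError(
            f"{len(missing)} network node(s) missing from feature table: {shown}"
        )
    extra = len(table.index.difference(net.node_ids))
    if extra:
        logger.info("dropping %d feature rows not in the network", extra)
    values = table.loc[list(net.node_ids)].to_numpy(dtype=float)
    return FeatureMatrix(values)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def read_labels(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def make_label_set(net: PPINetwork, positive_ids: Sequence[str]) -> LabelSet:
    """Map positive protein IDs onto the network; IDs absent from the graph
    are ignored with a log line (curated lists routinely exceed the LCC)."""
    idx = {n: i for i, n in enumerate(net.node_ids)}
    pos = frozenset(idx[p] for p in positive_ids if p in idx)
    dropped = len(set(positive_ids)) - len(pos)
    if dropped:
        logger.info("dropping %d positive label(s) not in the network", dropped)
    unl = frozenset(range(net.n_nodes)) - pos
    return LabelSet(pos, unl)


def read_gmt(paths_by_category: Mapping[str, str | Path]) -> AnnotationSets:
    """Read one GMT file per category: term <TAB> description <TAB> members."""
    categories: dict[str, dict[str, frozenset[str]]] = {}
    names: dict[str, str] = {}
    for cat, path in paths_by_category.items():
        terms: dict[str, frozenset[str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not line.strip():
                    continue
                term, desc, members = parts[0], parts[1], parts[2:]
                members = [m for m in members if m]
                terms[term] = frozenset(members)
                names[term] = desc
        categories[cat] = terms
    return AnnotationSets(categories, names)


def write_gmt(terms: Mapping[str, Iterable[str]],
              path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for term in sorted(terms):
            members = "\t".join(sorted(terms[term]))
            fh.write(f"{term}\t{descriptions.get(term, term)}\t{members}\n")


def apply_id_mapping(
    records: Iterable[tuple[str, str, float]],
    mapping: Mapping[str, str],
) -> list[tuple[str, str, float]]:
    """Harmonize edge-record IDs through a two-column mapping (old -> new);
    IDs absent from the mapping pass through unchanged."""
    return [(mapping.get(a, a), mapping.get(b, b), s) for a, b, s in records]
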