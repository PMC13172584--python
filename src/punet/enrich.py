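"""Hypergeometric over-representation analysis and candidate refinement.

Each annotation term is tested for over-representation in a candidate set
against the full-network background (upper-tail hypergeometric, equivalent
to one-sided Fisher's exact). P values are Benjamini-Hochberg corrected
within each category. A term is retained when it clears all four thresholds
(FDR <= 0.001, fold enrichment > 1, foreground count >= 5, background count
<= 500), and a candidate survives refinement only if every category with at
least one retained term covers it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .graph import AnnotationSets

__all__ = [
    "RetentionThresholds",
    "hypergeom_pvalue",
    "fold_enrichment",
    "bh_adjust",
    "enrich_category",
    "enrich_all",
    "refine_candidates",
]


@dataclass(frozen=True)
class RetentionThresholds:
    """The four retention criteria for a high-confidence term."""

    max_fdr: float = 0.001          # inclusive
    min_fold: float = 1.0           # strict
    min_fg_count: int = 5           # inclusive
    max_bg_count: int = 500         # inclusive


def hypergeom_pvalue(fg_hits: int, fg_size: int, bg_hits: int, bg_size: int) -> float:
    """Upper-tail P(X >= fg_hits) for X ~ Hypergeom(bg_size, bg_hits, fg_size)."""
    if not (0 <= fg_hits <= fg_size <= bg_size and fg_hits <= bg_hits <= bg_size):
        raise ValueError(
            f"inconsistent counts: fg {fg_hits}/{fg_size}, bg {bg_hits}/{bg_size}")
    return float(hypergeom.sf(fg_hits - 1, bg_size, bg_hits, fg_size))


def fold_enrichment(fg_hits: int, fg_size: int, bg_hits: int, bg_size: int) -> float:
    """Foreground rate over background rate: (fg_hits/fg_size)/(bg_hits/bg_size)."""
    if fg_size == 0 or bg_hits == 0 or bg_size == 0:
        raise ValueError("zero denominator in fold enrichment")
    return (fg_hits / fg_size) / (bg_hits / bg_size)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, clamped <= 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_category(
    protein_set: set[str],
    terms: Mapping[str, frozenset[str] | set[str]],
    background: set[str],
    category: str = "",
    thresholds: RetentionThresholds | None = None,
) -> pd.DataFrame:
    """Per-term enrichment of ``protein_set`` against ``background``.

    Term member sets are intersected with the background first; BH
    correction is applied within the category. Returns one row per term
    with counts, fold enrichment, p, fdr and the retained flag.
    """
    thresholds = thresholds or RetentionThresholds()
    if not protein_set:
        raise ValueError("empty protein set")
    if not protein_set <= background:
        raise ValueError("protein set must be a subset of the background")
    fg_size = len(protein_set)
    bg_size = len(background)
    rows = []
    for term in sorted(terms):
        members = set(terms[term]) & background
        bg_count = len(members)
        if bg_count == 0:
            continue
        fg_count = len(members & protein_set)
        p = hypergeom_pvalue(fg_count, fg_size, bg_count, bg_size)
        fold = fold_enrichment(fg_count, fg_size, bg_count, bg_size)
        rows.append({
            "category": category, "term": term,
            "fg_count": fg_count, "fg_size": fg_size,
            "bg_count": bg_count, "bg_size": bg_size,
            "fold_enrichment": fold, "p_value": p,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["fdr"] = bh_adjust(df["p_value"].to_numpy())
    df["retained"] = (
        (df["fdr"] <= thresholds.max_fdr)
        & (df["fold_enrichment"] > thresholds.min_fold)
        & (df["fg_count"] >= thresholds.min_fg_count)
        & (df["bg_count"] <= thresholds.max_bg_count)
    )
    return df


def enrich_all(
    protein_set: set[str],
    annotations: AnnotationSets,
    background: set[str],
    thresholds: RetentionThresholds | None = None,
) -> pd.DataFrame:
    """Enrichment across every annotation category, concatenated."""
    frames = [
        enrich_category(protein_set, terms, background, cat, thresholds)
        for cat, terms in annotations.categories.items()
    ]
    frames = [f for f in frames if not f.empty]
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def refine_candidates(
    candidates: set[str],
    table: pd.DataFrame,
    annotations: AnnotationSets,
) -> tuple[set[str], pd.DataFrame]:
    """Intersection refinement across annotation categories.

    A candidate survives iff, for every category that has at least one
    retained term, it belongs to at least one retained term of that
    category; categories with no retained term are vacuous. The coverage
    report lists, per candidate, the retained terms that cover it in each
    category, making the intersection semantics auditable.
    """
    if table.empty or not table["retained"].any():
        return set(), pd.DataFrame(
            columns=["node", "kept", "category", "covering_terms"])
    retained = table[table["retained"]]
    active = sorted(retained["category"].unique())
    cover_rows = []
    kept: set[str] = set()
    for node in sorted(candidates):
        covered_everywhere = True
        node_rows = []
        for cat in active:
            terms = retained[retained["category"] == cat]["term"]
            covering = sorted(
                t for t in terms
                if node in annotations.categories[cat][t]
            )
            node_rows.append((cat, covering))
            if not covering:
                covered_everywhere = False
        if covered_everywhere:
            kept.add(node)
        for cat, covering in node_rows:
            cover_rows.append({
                "node": node, "kept": covered_everywhere,
                "category": cat, "covering_terms": ";".join(covering),
            })
    return kept, pd.DataFrame(cover_rows)
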