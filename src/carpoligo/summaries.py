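"""Enrichment scores and directional category summaries.

The cluster enrichment score is the negative log10 of the geometric mean of
the constituent term p-values, computed as the arithmetic mean of -log10 p
(algebraically identical, numerically safer); clusters with ES >= 1.3 are
regarded as significantly enriched (~ p < 0.05). Category direction
summaries report up/down/unchanged gene counts and the mean and median logFC
per functional category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EnrichmentCluster",
    "CategorySummary",
    "ES_THRESHOLD",
    "enrichment_score",
    "score_cluster",
    "category_direction_summary",
    "percent",
    "biotype_composition",
    "baseline_sign_summary",
]

logger = logging.getLogger(__name__)

ES_THRESHOLD = 1.3


@dataclass(frozen=True)
class EnrichmentCluster:
    cluster_id: str
    term_p_values: tuple[float, ...]
    enrichment_score: float
    significant: bool


@dataclass(frozen=True)
class CategorySummary:
    category_id: str
    n_genes: int
    n_up: int
    n_down: int
    n_unchanged: int
    mean_logfc: float
    median_logfc: float


def enrichment_score(p_values) -> float:
    """ES = mean of -log10(p) over the cluster's terms."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return float(np.mean(-np.log10(p)))


def score_cluster(cluster_id: str, p_values, threshold: float = ES_THRESHOLD) -> EnrichmentCluster:
    es = enrichment_score(p_values)
    return EnrichmentCluster(cluster_id, tuple(float(p) for p in p_values), es, es >= threshold)


def category_direction_summary(category_id: str, gene_ids, logfc: dict | pd.Series) -> CategorySummary:
    """Up/down/unchanged counts and mean/median logFC for one category.

    Genes without a logFC are dropped with a logged count; logFC exactly 0
    counts as unchanged.
    """
    lf = pd.Series(dict(logfc) if not isinstance(logfc, pd.Series) else logfc)
    present = [g for g in gene_ids if g in lf.index]
    dropped = len(list(gene_ids)) - len(present)
    if dropped:
        logger.info("category %s: dropped %d genes without logFC", category_id, dropped)
    if not present:
        raise ValueError(f"category {category_id!r} empty after dropping unmapped genes")
    vals = lf.loc[present].astype(float)
    return CategorySummary(
        category_id=category_id,
        n_genes=len(present),
        n_up=int((vals > 0).sum()),
        n_down=int((vals < 0).sum()),
        n_unchanged=int((vals == 0).sum()),
        mean_logfc=float(vals.mean()),
        median_logfc=float(vals.median()),
    )


def percent(part: float, whole: float, ndigits: int = 2) -> float:
    """Percentage of ``part`` in ``whole``, rounded to ``ndigits``."""
    if whole == 0:
        raise ValueError("whole must be non-zero")
    return round(100.0 * part / whole, ndigits)


def biotype_composition(biotypes, ndigits: int = 2) -> pd.DataFrame:
    """Count and percentage per biotype class (mRNA/ncRNA/miscRNA/...)."""
    s = pd.Series(list(biotypes))
    counts = s.value_counts()
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "count": counts,
            "percent": [percent(c, total, ndigits) for c in counts],
        }
    )


def baseline_sign_summary(values, ndigits: int = 1) -> dict:
    """How many features sit above/below the cross-array baseline."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty values")
    n_pos = int((v > 0).sum())
    n_neg = int((v < 0).sum())
    return {
        "n": int(v.size),
        "n_positive": n_pos,
        "n_negative": n_neg,
        "pct_positive": percent(n_pos, v.size, ndigits),
        "pct_negative": percent(n_neg, v.size, ndigits),
    }
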