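"""Per-cell quality control and preliminary cell/gene filters.

Cells are removed when strictly below 50% uniquely mapped reads or strictly
above 50% mitochondrial reads; boundary values pass (the removal rules are
strict inequalities). Genes are kept when expressed in at least
``min_cells_per_gene`` cells. The per-cell detected-feature minimum is
computed and flagged but, by default, not enforced — on the cohorts this
pipeline targets it removes nothing; a strict mode enforces it.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import AlignmentStats, CountMatrix

__all__ = [
    "QCThresholds",
    "compute_cell_qc",
    "filter_cells",
    "filter_genes",
    "detection_summary",
    "default_mito_genes",
]

MITO_PREFIX = "MT-"


@dataclasses.dataclass(frozen=True)
class QCThresholds:
    """Cell/gene QC thresholds.

    min_unique_map_pct : cells strictly below are removed (percent).
    max_mito_pct       : cells strictly above are removed (percent).
    min_cells_per_gene : genes expressed in fewer cells are removed.
    min_features_per_cell : cells with fewer detected genes are flagged
        (removed only in strict mode).
    """

    min_unique_map_pct: float = 50.0
    max_mito_pct: float = 50.0
    min_cells_per_gene: int = 5
    min_features_per_cell: int = 1000

    def __post_init__(self) -> None:
        if not (0 <= self.min_unique_map_pct <= 100 and 0 <= self.max_mito_pct <= 100):
            raise ValueError("percent thresholds must lie in [0, 100]")
        if self.min_cells_per_gene < 0 or self.min_features_per_cell < 0:
            raise ValueError("count thresholds must be >= 0")


def default_mito_genes(gene_ids: Iterable[str], prefix: str = MITO_PREFIX) -> set[str]:
    """Mitochondrial gene set by symbol prefix (human convention ``MT-``)."""
    return {g for g in gene_ids if g.startswith(prefix)}


def compute_cell_qc(
    counts: CountMatrix,
    stats: AlignmentStats | None = None,
    mito_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Per-cell QC table: n_genes, mito_pct, unique_map_pct, zero_total flag.

    ``mito_pct`` is 100 x (counts on mitochondrial genes) / (total counts)
    per cell; cells with zero total counts get ``mito_pct = 0`` and are
    flagged ``zero_total``. ``unique_map_pct`` is copied from the alignment
    stats and is NaN where absent.
    """
    if mito_genes is None:
        mito_genes = default_mito_genes(counts.gene_ids)
    mito_mask = np.array([g in mito_genes for g in counts.gene_ids])
    total = counts.counts.sum(axis=0).astype(float)
    mito = counts.counts[mito_mask].sum(axis=0).astype(float) if mito_mask.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(total > 0, 100.0 * mito / total, 0.0)
    n_genes = (counts.counts > 0).sum(axis=0)
    umap = np.full(counts.n_cells, np.nan)
    if stats is not None:
        for i, c in enumerate(counts.cell_ids):
            if c in stats.unique_map_pct:
                umap[i] = stats.unique_map_pct[c]
    return pd.DataFrame(
        {
            "n_genes": n_genes,
            "mito_pct": mito_pct,
            "unique_map_pct": umap,
            "zero_total": total == 0,
        },
        index=pd.Index(counts.cell_ids, name="cell_id"),
    )


def filter_cells(
    qc: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
    strict_features: bool = False,
) -> tuple[list[str], dict[str, list[str]]]:
    """Apply cell filters; return (kept cell ids, removal reasons).

    A cell is removed iff ``unique_map_pct < min_unique_map_pct`` (when the
    stat is present) or ``mito_pct > max_mito_pct``; values exactly at the
    threshold are kept. Zero-total cells are removed with a dedicated
    reason. Each removed cell carries every reason that applies.
    """
    kept: list[str] = []
    removed: dict[str, list[str]] = {}
    for cell, row in qc.iterrows():
        reasons = []
        if np.isfinite(row["unique_map_pct"]) and row["unique_map_pct"] < thresholds.min_unique_map_pct:
            reasons.append("low_unique_mapping")
        if row["mito_pct"] > thresholds.max_mito_pct:
            reasons.append("high_mitochondrial")
        if row["zero_total"]:
            reasons.append("zero_total_counts")
        if strict_features and row["n_genes"] < thresholds.min_features_per_cell:
            reasons.append("low_feature_count")
        if reasons:
            removed[str(cell)] = reasons
        else:
            kept.append(str(cell))
    return kept, removed


def filter_genes(counts: CountMatrix, min_cells: int = 5) -> CountMatrix:
    """Retain genes expressed (count > 0) in at least ``min_cells`` cells."""
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    n_expr = (counts.counts > 0).sum(axis=1)
    keep = [g for g, n in zip(counts.gene_ids, n_expr) if n >= min_cells]
    return counts.subset(genes=keep)


def detection_summary(counts: CountMatrix, cell_subset: Sequence[str] | None = None) -> dict[str, float]:
    """Median / min / max / mean of per-cell detected-gene counts."""
    idx = counts.cell_indices(cell_subset)
    if idx.size == 0:
        raise ValueError("detection_summary needs a non-empty cell subset")
    n_genes = (counts.counts[:, idx] > 0).sum(axis=0)
    return {
        "median": float(np.median(n_genes)),
        "min": float(n_genes.min()),
        "max": float(n_genes.max()),
        "mean": float(n_genes.mean()),
        "n_cells": int(idx.size),
    }
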