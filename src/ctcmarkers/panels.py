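"""Detection statistics for marker genes and marker cocktails.

Detection is defined on raw counts: a gene is detected in a cell when its
count is at least ``min_count`` (default 1). Size-factor normalization
preserves zeros, so detection fractions are invariant under it. A cell is
covered by a panel when any member is detected; ``n_missed`` counts the
cells covered by no member.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = ["PanelStats", "detection_fraction", "panel_coverage", "candidate_summary"]

PUBLISHED_PANEL = ("EPCAM", "HER2", "EGFR")
NEW_PANEL = ("AHNAK2", "CAVIN1", "ODR4", "TRIML2")
TOTAL_PANEL = PUBLISHED_PANEL + NEW_PANEL


@dataclasses.dataclass
class PanelStats:
    """Per-marker detection counts plus panel-level miss count."""

    per_marker: pd.DataFrame  # index: gene; columns: n_detected, n_cells, fraction
    n_missed: int
    n_cells: int

    @property
    def coverage(self) -> float:
        """Fraction of cells detecting at least one panel member."""
        return 1.0 - self.n_missed / self.n_cells


def detection_fraction(
    counts: CountMatrix,
    gene: str,
    cell_subset: Sequence[str] | None = None,
    min_count: int = 1,
) -> tuple[float, int, int]:
    """Return (fraction, n_detected, n_cells) for one gene over a subset."""
    gi = counts.gene_index(gene)
    idx = counts.cell_indices(cell_subset)
    if idx.size == 0:
        raise ValueError("detection_fraction needs a non-empty cell subset")
    n_det = int((counts.counts[gi, idx] >= min_count).sum())
    return n_det / idx.size, n_det, int(idx.size)


def panel_coverage(
    counts: CountMatrix,
    panel: Sequence[str],
    cell_subset: Sequence[str] | None = None,
    min_count: int = 1,
) -> PanelStats:
    """Per-marker detection plus the number of cells missed by the panel."""
    if not panel:
        raise ValueError("panel must contain at least one gene")
    idx = counts.cell_indices(cell_subset)
    if idx.size == 0:
        raise ValueError("panel_coverage needs a non-empty cell subset")
    rows = []
    detected_any = np.zeros(idx.size, dtype=bool)
    for g in panel:
        gi = counts.gene_index(g)
        det = counts.counts[gi, idx] >= min_count
        detected_any |= det
        rows.append({"gene": g, "n_detected": int(det.sum()), "n_cells": int(idx.size), "fraction": det.mean()})
    per_marker = pd.DataFrame(rows).set_index("gene")
    return PanelStats(per_marker=per_marker, n_missed=int((~detected_any).sum()), n_cells=int(idx.size))


def candidate_summary(
    counts: CountMatrix,
    candidates: Sequence[str],
    cell_subset: Sequence[str] | None = None,
    min_count: int = 1,
) -> pd.DataFrame:
    """Detection fraction per candidate; the ``min`` row carries the worst
    coverage across the set (the 'each expressed by at least X%' statistic)."""
    if not candidates:
        raise ValueError("candidate_summary needs a non-empty candidate list")
    rows = []
    for g in candidates:
        frac, n_det, n = detection_fraction(counts, g, cell_subset, min_count)
        rows.append({"gene": g, "n_detected": n_det, "n_cells": n, "fraction": frac})
    df = pd.DataFrame(rows).set_index("gene")
    df.attrs["min_fraction"] = float(df["fraction"].min())
    return df
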