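"""The candidate-surface-marker filter cascade.

Starting from every gene expressed in the tumor-cell (CTC) compartment, the
cascade removes, in order: genes with any PBMC single-cell expression, genes
with whole-blood expression above 15, genes with low mean normalized
expression in CTCs (below 8, or outside the top 5% in percentile mode),
genes detected in fewer than 30% of CTCs, non-protein-coding genes, genes
not annotated to the plasma membrane, and finally genes outside a manually
curated keep-list (surface-staining evidence and antibody availability are
not computable). Known markers on a whitelist (e.g. EGFR) are appended to
the final candidates with a ``known`` flag.

All removal rules are strict inequalities: a gene exactly at a threshold
survives. Stages are nested (each output is a subset of its input), so
counts decrease weakly along the cascade, and the final set in threshold
mode is invariant under reordering the membership filters.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np

from .io import BloodReference, CountMatrix, GeneAnnotation
from .normalization import NormalizedMatrix, mean_normalized_expression, normalize_log2, size_factors

logger = logging.getLogger(__name__)

__all__ = [
    "CascadeConfig",
    "CascadeStage",
    "CascadeResult",
    "drop_unexpressed",
    "subtract_pbmc_expressed",
    "subtract_whole_blood",
    "filter_by_expression",
    "filter_by_coverage",
    "filter_protein_coding",
    "filter_plasma_membrane",
    "apply_curation",
    "run_cascade",
]

_EPS = 1e-12  # guards float round-off at fraction boundaries


@dataclasses.dataclass(frozen=True)
class CascadeConfig:
    """Thresholds for every cascade stage.

    pbmc_count_min_excl : genes with PBMC max count strictly above this are
        removed (default 0: any PBMC expression disqualifies).
    blood_expr_max : whole-blood expression cap, TPM-like units; strictly
        above is removed.
    min_mean_expr : mean normalized CTC expression floor; strictly below is
        removed (threshold mode).
    top_pct : percentile-mode alternative — keep the top 5% of genes by
        mean expression, ties at the cutoff all retained.
    expression_mode : "threshold" (default) or "percentile".
    min_detect_frac : minimum fraction of CTCs detecting the gene; strictly
        below is removed.
    detection_min_count : a gene is detected in a cell when its raw count is
        at least this (default 1).
    """

    pbmc_count_min_excl: float = 0.0
    blood_expr_max: float = 15.0
    min_mean_expr: float = 8.0
    top_pct: float = 5.0
    expression_mode: str = "threshold"
    min_detect_frac: float = 0.30
    detection_min_count: int = 1
    required_biotype: str = "protein_coding"
    required_location: str = "plasma_membrane"
    expression_scale: str = "linear"  # or "log2"

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_detect_frac <= 1.0):
            raise ValueError("min_detect_frac must lie in [0, 1]")
        for f in ("pbmc_count_min_excl", "blood_expr_max", "min_mean_expr", "top_pct"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.expression_mode not in ("threshold", "percentile"):
            raise ValueError("expression_mode must be 'threshold' or 'percentile'")


@dataclasses.dataclass
class CascadeStage:
    name: str
    input_genes: frozenset[str]
    surviving: frozenset[str]

    @property
    def count(self) -> int:
        return len(self.surviving)


@dataclasses.dataclass
class CascadeResult:
    """Ordered stage record; stage k+1's input is stage k's output."""

    stages: list[CascadeStage]
    final_candidates: list[dict]
    known_markers: frozenset[str]
    config_snapshot: dict

    @property
    def stage_counts(self) -> dict[str, int]:
        return {st.name: st.count for st in self.stages}

    @property
    def candidate_genes(self) -> list[str]:
        return [c["gene"] for c in self.final_candidates]

    def validate_nesting(self) -> None:
        prev = None
        for st in self.stages:
            if not st.surviving <= st.input_genes:
                raise AssertionError(f"stage {st.name}: output not a subset of input")
            if prev is not None and st.input_genes != prev.surviving:
                raise AssertionError(f"stage {st.name}: input differs from previous output")
            prev = st


def drop_unexpressed(counts: CountMatrix, cell_subset: Sequence[str] | None = None) -> frozenset[str]:
    """Genes with any nonzero count over the cell subset (mean count > 0)."""
    idx = counts.cell_indices(cell_subset)
    if idx.size == 0:
        raise ValueError("drop_unexpressed needs a non-empty cell subset")
    expressed = (counts.counts[:, idx] > 0).any(axis=1)
    return frozenset(g for g, e in zip(counts.gene_ids, expressed) if e)


def subtract_pbmc_expressed(
    genes: frozenset[str], ref: BloodReference, max_count: float = 0.0
) -> frozenset[str]:
    """Remove genes with PBMC single-cell count strictly above ``max_count``.

    Genes absent from the reference are treated as PBMC count 0 and kept.
    """
    return frozenset(g for g in genes if ref.lookup(g)[0] <= max_count)


def subtract_whole_blood(genes: frozenset[str], ref: BloodReference, max_expr: float = 15.0) -> frozenset[str]:
    """Remove genes with whole-blood expression strictly above ``max_expr``."""
    return frozenset(g for g in genes if ref.lookup(g)[1] <= max_expr)


def filter_by_expression(
    genes: frozenset[str], mean_expr: Mapping[str, float], cfg: CascadeConfig = CascadeConfig()
) -> frozenset[str]:
    """Expression filter: threshold mode keeps mean >= ``min_mean_expr``;
    percentile mode keeps the top ``top_pct`` percent of the input set, all
    ties at the cutoff retained."""
    missing = [g for g in genes if g not in mean_expr]
    if missing:
        raise KeyError(f"mean expression missing for genes: {sorted(missing)[:5]}")
    if cfg.expression_mode == "threshold":
        return frozenset(g for g in genes if mean_expr[g] >= cfg.min_mean_expr)
    values = np.array([mean_expr[g] for g in genes])
    if values.size == 0:
        return frozenset()
    cutoff = float(np.percentile(values, 100.0 - cfg.top_pct, method="higher"))
    return frozenset(g for g in genes if mean_expr[g] >= cutoff)


def filter_by_coverage(
    genes: frozenset[str],
    counts: CountMatrix,
    cell_subset: Sequence[str] | None = None,
    cfg: CascadeConfig = CascadeConfig(),
) -> frozenset[str]:
    """Keep genes detected (count >= detection_min_count) in at least
    ``min_detect_frac`` of the subset cells; a fraction exactly at the
    threshold survives."""
    idx = counts.cell_indices(cell_subset)
    if idx.size == 0:
        raise ValueError("filter_by_coverage needs a non-empty cell subset")
    gpos = {g: i for i, g in enumerate(counts.gene_ids)}
    sub = counts.counts[:, idx]
    out = set()
    for g in genes:
        gi = gpos.get(g)
        if gi is None:
            continue  # gene not in matrix cannot be detected
        n_det = int((sub[gi] >= cfg.detection_min_count).sum())
        if n_det >= cfg.min_detect_frac * idx.size - _EPS:
            out.add(g)
    return frozenset(out)


def filter_protein_coding(
    genes: frozenset[str], ann: GeneAnnotation, biotype: str = "protein_coding"
) -> frozenset[str]:
    """Keep genes with the required biotype; unannotated genes are removed
    (unknown is not protein-coding) and logged."""
    missing = sorted(g for g in genes if g not in ann)
    if missing:
        logger.info("biotype filter: %d genes missing from annotation removed (e.g. %s)", len(missing), missing[:3])
    return frozenset(g for g in genes if ann.biotype(g) == biotype)


def filter_plasma_membrane(
    genes: frozenset[str], ann: GeneAnnotation, location: str = "plasma_membrane"
) -> frozenset[str]:
    """Keep genes whose annotated locations include the plasma membrane
    (membership, not exclusivity); unannotated genes are removed."""
    return frozenset(g for g in genes if location in ann.locations(g))


def apply_curation(
    genes: frozenset[str],
    keep_list: Sequence[str] | None,
    whitelist: Sequence[str] = (),
) -> tuple[frozenset[str], list[dict]]:
    """Intersect survivors with the user-supplied curation keep-list and
    append whitelist entries (known markers) flagged ``known``.

    Curation entries absent from the surviving set raise a warning-level
    log, not an error. ``keep_list=None`` means no curation was performed
    (all survivors pass)."""
    if keep_list is None:
        kept = set(genes)
    else:
        stray = sorted(set(keep_list) - set(genes))
        if stray:
            logger.warning("curation list entries not among cascade survivors: %s", stray[:5])
        kept = set(genes) & set(keep_list)
    candidates = [{"gene": g, "known": False} for g in sorted(kept)]
    for w in whitelist:
        if w not in kept:
            candidates.append({"gene": w, "known": True})
        else:
            for c in candidates:
                if c["gene"] == w:
                    c["known"] = True
    return frozenset(kept), candidates


def run_cascade(
    counts: CountMatrix,
    blood_ref: BloodReference,
    annotation: GeneAnnotation,
    cfg: CascadeConfig = CascadeConfig(),
    curation: Sequence[str] | None = None,
    whitelist: Sequence[str] = (),
    cell_subset: Sequence[str] | None = None,
    normalized: NormalizedMatrix | None = None,
) -> CascadeResult:
    """Execute the full cascade in its fixed stage order.

    ``cell_subset`` names the CTC cells over which expression and coverage
    are computed (all cells if None). ``normalized`` may be supplied to
    reuse a precomputed normalization; otherwise positive-counts
    median-of-ratios size factors are computed here.
    """
    stages: list[CascadeStage] = []

    def record(name, input_set, output_set):
        stages.append(CascadeStage(name, frozenset(input_set), frozenset(output_set)))
        return frozenset(output_set)

    try:
        if normalized is None:
            normalized = normalize_log2(counts, size_factors(counts, mode="positive"))
        mean_expr = mean_normalized_expression(normalized, cell_subset, scale=cfg.expression_scale)
        g0 = frozenset(counts.gene_ids)
        g = record("expressed", g0, drop_unexpressed(counts, cell_subset))
        g = record("pbmc_subtracted", g, subtract_pbmc_expressed(g, blood_ref, cfg.pbmc_count_min_excl))
        g = record("blood_subtracted", g, subtract_whole_blood(g, blood_ref, cfg.blood_expr_max))
        g = record("expression", g, filter_by_expression(g, mean_expr, cfg))
        g = record("coverage", g, filter_by_coverage(g, counts, cell_subset, cfg))
        g = record("protein_coding", g, filter_protein_coding(g, annotation, cfg.required_biotype))
        g = record("plasma_membrane", g, filter_plasma_membrane(g, annotation, cfg.required_location))
        kept, candidates = apply_curation(g, curation, whitelist)
        record("curated", g, kept)
    except Exception as e:
        stage_name = stages[-1].name if stages else "expressed"
        raise RuntimeError(f"cascade failed after stage {stage_name!r}: {e}") from e

    result = CascadeResult(
        stages=stages,
        final_candidates=candidates,
        known_markers=frozenset(w for w in whitelist),
        config_snapshot=dataclasses.asdict(cfg),
    )
    result.validate_nesting()
    return result
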