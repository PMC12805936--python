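"""End-to-end orchestration: QC -> gene filter -> normalization -> cascade
-> panel statistics, assembled into one machine-readable report.

``run_full_screen`` works on in-memory objects (a :class:`StudyBundle` or
the individual containers); ``run_full_screen_from_paths`` loads the file
artifacts first. Reports are deterministic for fixed inputs — timestamps
live in a separate field so two runs on the same inputs differ only there.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from typing import Mapping, Sequence

from .cascade import CascadeConfig, CascadeResult, run_cascade
from .io import AlignmentStats, BloodReference, CountMatrix, GeneAnnotation
from .normalization import normalize_log2, size_factors
from .panels import NEW_PANEL, PUBLISHED_PANEL, TOTAL_PANEL, panel_coverage
from .qc import QCThresholds, compute_cell_qc, detection_summary, filter_cells, filter_genes

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ScreenReport", "run_full_screen", "run_validation_quant"]

REPORT_SCHEMA_VERSION = 1


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Thresholds and panel definitions for a full screen run."""

    qc: QCThresholds = QCThresholds()
    cascade: CascadeConfig = CascadeConfig()
    panels: Mapping[str, tuple[str, ...]] = dataclasses.field(
        default_factory=lambda: {"published": PUBLISHED_PANEL, "new": NEW_PANEL, "total": TOTAL_PANEL}
    )
    curation: Sequence[str] | None = None
    whitelist: Sequence[str] = ()
    normalization_mode: str = "positive"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, panel in self.panels.items():
            if not panel:
                raise ValueError(f"panel {name!r} is empty")


@dataclasses.dataclass
class ScreenReport:
    """Assembled results of one full screen run."""

    qc_summary: dict
    cascade: CascadeResult
    panel_stats: dict
    candidate_genes: list[str]
    config: dict
    timestamp: str

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "qc_summary": self.qc_summary,
            "cascade": {
                "stage_counts": self.cascade.stage_counts,
                "stages": [
                    {"name": st.name, "n_surviving": st.count, "surviving": sorted(st.surviving)}
                    for st in self.cascade.stages
                ],
                "final_candidates": self.cascade.final_candidates,
            },
            "panel_stats": self.panel_stats,
            "candidate_genes": self.candidate_genes,
            "config": self.config,
            "timestamp": self.timestamp,
        }


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the failing stage named."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_full_screen(
    counts: CountMatrix,
    stats: AlignmentStats | None,
    blood_ref: BloodReference,
    annotation: GeneAnnotation,
    cfg: RunConfig = RunConfig(),
) -> ScreenReport:
    """Run QC, gene filtering, normalization, the cascade and panel stats.

    The cascade's expression and coverage statistics are computed over the
    QC-passing CTC cells (cells in group ``"CTC"`` when groups are present,
    every kept cell otherwise). Any stage failure aborts with the stage
    named in the error.
    """
    with _stage("qc"):
        qc = compute_cell_qc(counts, stats)
        kept, removed = filter_cells(qc, cfg.qc)
        if not kept:
            raise ValueError("no cells pass QC")
    with _stage("gene_filter"):
        filtered = counts.subset(cells=kept)
        filtered = filter_genes(filtered, cfg.qc.min_cells_per_gene)
    with _stage("normalization"):
        sf = size_factors(filtered, mode=cfg.normalization_mode)
        norm = normalize_log2(filtered, sf)
    if counts.cell_groups is not None:
        ctc_cells = [c for c in filtered.cell_ids if counts.cell_groups.get(c) == "CTC"]
    else:
        ctc_cells = list(filtered.cell_ids)
    if not ctc_cells:
        raise _StageError("stage 'cascade' failed: no CTC cells after QC")
    with _stage("cascade"):
        cascade = run_cascade(
            filtered,
            blood_ref,
            annotation,
            cfg.cascade,
            curation=cfg.curation,
            whitelist=cfg.whitelist,
            cell_subset=ctc_cells,
            normalized=norm,
        )
    panel_stats = {}
    with _stage("panels"):
        for name, panel in cfg.panels.items():
            present = [g for g in panel if g in filtered.gene_ids]
            if not present:
                panel_stats[name] = {"note": "no panel gene present in matrix"}
                continue
            ps = panel_coverage(filtered, present, ctc_cells)
            panel_stats[name] = {
                "genes": list(present),
                "per_marker": {
                    g: {"n_detected": int(r["n_detected"]), "fraction": float(r["fraction"])}
                    for g, r in ps.per_marker.iterrows()
                },
                "n_missed": ps.n_missed,
                "n_cells": ps.n_cells,
                "coverage": ps.coverage,
            }

    det = detection_summary(filtered, ctc_cells)
    qc_summary = {
        "n_cells_input": counts.n_cells,
        "n_cells_kept": len(kept),
        "removed": removed,
        "n_genes_input": counts.n_genes,
        "n_genes_after_filter": filtered.n_genes,
        "n_ctc_cells": len(ctc_cells),
        "detection": det,
        "thresholds": dataclasses.asdict(cfg.qc),
    }
    return ScreenReport(
        qc_summary=qc_summary,
        cascade=cascade,
        panel_stats=panel_stats,
        candidate_genes=cascade.candidate_genes,
        config={
            "qc": dataclasses.asdict(cfg.qc),
            "cascade": dataclasses.asdict(cfg.cascade),
            "panels": {k: list(v) for k, v in cfg.panels.items()},
            "normalization_mode": cfg.normalization_mode,
            "seed": cfg.seed,
        },
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )


def run_validation_quant(
    image_jobs: Sequence[dict] = (),
    event_jobs: Sequence[dict] = (),
) -> dict:
    """Quantify marker staining across images and gated event tables.

    ``image_jobs``: dicts with keys ``image`` (ImageStack), ``seg_config``
    (SegmentationConfig), ``scheme`` (ClassScheme), ``population``,
    ``marker_channel``, ``cutoff`` and optional ``name``/``panel``.
    ``event_jobs``: dicts with ``events`` (EventTable), ``gate_config``
    (GateConfig) and optional ``name``/``panel``.

    Returns per-job percent-positive (images) or gated fractions (events),
    plus a pooled percent-positive per panel — the cell-weighted mean of
    the per-image percentages.
    """
    from .imagequant import classify_cells, gate_events, measure_cells, percent_positive, segment_nuclei

    if not image_jobs and not event_jobs:
        raise ValueError("run_validation_quant needs at least one image or event job")
    report: dict = {"images": [], "events": [], "pooled": {}}
    pooled: dict[str, list[tuple[int, float]]] = {}
    for i, job in enumerate(image_jobs):
        mask = segment_nuclei(job["image"], job["seg_config"])
        meas = measure_cells(mask, job["image"])
        classes = classify_cells(meas, job["scheme"])
        pop = job.get("population", "ctc")
        pct = percent_positive(meas, classes, pop, job.get("marker_channel", "marker"), job["cutoff"])
        n_pop = sum(1 for c in classes.values() if c == pop)
        entry = {
            "name": job.get("name", f"image{i}"),
            "panel": job.get("panel"),
            "n_cells": len(meas),
            "n_population": n_pop,
            "percent_positive": pct,
            "class_counts": {c: sum(1 for v in classes.values() if v == c) for c in set(classes.values())},
        }
        report["images"].append(entry)
        if job.get("panel"):
            pooled.setdefault(job["panel"], []).append((n_pop, pct))
    for j, job in enumerate(event_jobs):
        res = gate_events(job["events"], job["gate_config"], job.get("marker_channel", "marker"))
        res["name"] = job.get("name", f"events{j}")
        res["panel"] = job.get("panel")
        report["events"].append(res)
    for panel, entries in pooled.items():
        total_n = sum(n for n, _ in entries)
        report["pooled"][panel] = {
            "n_cells": total_n,
            "percent_positive": sum(n * p for n, p in entries) / total_n if total_n else None,
        }
    return report
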