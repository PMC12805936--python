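"""Synthetic data with ground truth for every pipeline stage.

The count generator emulates the screen's study design: 37 tumor cells
(CTCs) plus 6 cultured control cells surviving QC, a handful of cells
planted to fail the mapping or mitochondrial filters, and a ~5,000–25,000
gene transcriptome drawn from per-gene negative-binomial models. Gene
classes carry the cascade's ground truth:

``true_marker``
    High mean (normalized average well above 8), detected in >=45% of
    CTCs, protein-coding, plasma-membrane, blood-negative — clears every
    filter with margin.
``decoy_<stage>``
    Violates exactly one named cascade filter (pbmc, blood, expression,
    coverage, biotype, location) and clears all others, so a cascade
    failure localizes to one stage.
``background_*``
    The rest of the transcriptome; each background gene fails at least one
    of the early filters by construction (PBMC-expressed, blood-high, or
    low expression), mirroring the fact that most genes are expressed in
    blood or weakly expressed in CTCs.

Zeros arise from low negative-binomial means; there is no separate dropout
process (full-length single-cell chemistry motivates this). Every
generator is a pure function of its config and seed. The generators do not
model gene–gene correlation or batch effects.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AlignmentStats, BloodReference, CountMatrix, EventTable, GeneAnnotation, ImageStack

__all__ = [
    "SimConfig",
    "ImageSimConfig",
    "FlowSimConfig",
    "SimTruth",
    "CASCADE_DECOY_STAGES",
    "simulate_ctc_counts",
    "simulate_references",
    "simulate_if_image",
    "simulate_flow_events",
    "simulate_full_study",
    "check_truth_consistency",
]

CASCADE_DECOY_STAGES = ("pbmc", "blood", "expression", "coverage", "biotype", "location")

MITO_GENES = (
    "MT-CO1", "MT-CO2", "MT-CO3", "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4",
    "MT-ND4L", "MT-ND5", "MT-ND6", "MT-CYB", "MT-ATP6", "MT-ATP8",
)


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the screened cohort: 41 CTCs of which 3 fail the
    uniquely-mapped-reads filter and 1 the mitochondrial filter (37
    survive), plus 6 cultured control cells. Negative-binomial means per
    gene class are chosen so each class clears or violates its intended
    filters with margin (true markers mean 30 counts, detection ~1;
    expression decoys mean 3, normalized average ~3 << 8).
    """

    n_ctc: int = 37
    n_control: int = 6
    n_qc_fail_mapping: int = 3
    n_qc_fail_mito: int = 1
    n_genes: int = 5000
    n_true_markers: int = 6
    decoy_stages: tuple[str, ...] = CASCADE_DECOY_STAGES
    marker_nb_mean: float = 30.0
    marker_nb_dispersion: float = 0.3
    lowexpr_nb_mean: float = 3.0
    lowexpr_nb_dispersion: float = 0.1
    coverage_decoy_frac: float = 0.15
    coverage_decoy_count_mean: float = 120.0
    background_nb_mean_log: float = 0.5  # lognormal params of background means
    background_nb_sigma_log: float = 1.0
    mito_nb_mean: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ctc < 1 or self.n_control < 1:
            raise ValueError("n_ctc and n_control must be >= 1")
        if not (0.0 <= self.coverage_decoy_frac <= 1.0):
            raise ValueError("coverage_decoy_frac must lie in [0, 1]")
        unknown = set(self.decoy_stages) - set(CASCADE_DECOY_STAGES)
        if unknown:
            raise ValueError(f"unknown decoy stages: {sorted(unknown)}")
        n_special = self.n_true_markers + len(self.decoy_stages) + len(MITO_GENES)
        if self.n_genes < n_special + 10:
            raise ValueError(f"n_genes must exceed {n_special + 10} to leave room for background genes")


@dataclasses.dataclass
class SimTruth:
    """Ground truth emitted alongside the synthetic artifacts."""

    gene_classes: dict[str, str]
    true_markers: list[str]
    decoys: dict[str, str]  # stage -> gene
    qc_fail_cells: dict[str, str]  # cell -> reason
    ctc_cells: list[str]  # CTCs passing QC
    control_cells: list[str]


def _nb(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    """Negative binomial with mean ``mean`` and variance mean + dispersion*mean^2."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion <= 0:
        return rng.poisson(mean, size=size).astype(np.int64)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size).astype(np.int64)


def simulate_ctc_counts(cfg: SimConfig = SimConfig()) -> tuple[CountMatrix, AlignmentStats, SimTruth]:
    """Draw the synthetic cohort's count matrix, alignment stats and truth.

    Cells planted to fail QC are labeled CTCs (the screened population);
    controls always pass. Identical config and seed give identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    n_ctc_total = cfg.n_ctc + cfg.n_qc_fail_mapping + cfg.n_qc_fail_mito
    ctc_ids = [f"CTC{i + 1:03d}" for i in range(n_ctc_total)]
    control_ids = [f"CL{i + 1}" for i in range(cfg.n_control)]
    cell_ids = ctc_ids + control_ids
    n_cells = len(cell_ids)

    # QC-fail assignments: mapping failures first, then the mito failure(s)
    qc_fail = {}
    for c in ctc_ids[: cfg.n_qc_fail_mapping]:
        qc_fail[c] = "low_unique_mapping"
    for c in ctc_ids[cfg.n_qc_fail_mapping : cfg.n_qc_fail_mapping + cfg.n_qc_fail_mito]:
        qc_fail[c] = "high_mitochondrial"
    passing_ctcs = [c for c in ctc_ids if c not in qc_fail]

    # gene roster
    markers = [f"MARK{i + 1}" for i in range(cfg.n_true_markers)]
    decoys = {st: f"DECOY_{st.upper()}" for st in cfg.decoy_stages}
    n_bg = cfg.n_genes - len(markers) - len(decoys) - len(MITO_GENES)
    background = [f"BG{i + 1:05d}" for i in range(n_bg)]
    gene_ids = markers + list(decoys.values()) + list(MITO_GENES) + background

    gene_classes = {g: "true_marker" for g in markers}
    gene_classes.update({g: f"decoy_{st}" for st, g in decoys.items()})
    gene_classes.update({g: "mito" for g in MITO_GENES})
    # background failure causes; most genes are blood-expressed
    bg_cause = rng.choice(
        ["background_pbmc", "background_blood", "background_lowexpr"], size=n_bg, p=[0.55, 0.1, 0.35]
    )
    gene_classes.update(dict(zip(background, bg_cause)))

    counts = np.zeros((len(gene_ids), n_cells), dtype=np.int64)
    gidx = {g: i for i, g in enumerate(gene_ids)}

    marker_like = markers + [decoys[st] for st in ("pbmc", "blood", "biotype", "location") if st in decoys]
    for g in marker_like:
        counts[gidx[g]] = _nb(rng, cfg.marker_nb_mean, cfg.marker_nb_dispersion, n_cells)
        # detection must clear 45% with certainty even in tiny cohorts
        zero = counts[gidx[g]] == 0
        counts[gidx[g], zero] = 1
    if "expression" in decoys:
        counts[gidx[decoys["expression"]]] = _nb(rng, cfg.lowexpr_nb_mean, cfg.lowexpr_nb_dispersion, n_cells)
        zero = counts[gidx[decoys["expression"]]] == 0
        counts[gidx[decoys["expression"]], zero] = 1  # coverage must not be the failing filter
    if "coverage" in decoys:
        # detected in a planted minority of QC-passing CTCs with large counts:
        # high mean expression but low coverage
        g = decoys["coverage"]
        n_det = max(5, int(np.floor(cfg.coverage_decoy_frac * len(passing_ctcs))))
        det_cells = rng.choice(passing_ctcs, size=n_det, replace=False)
        cpos = {c: j for j, c in enumerate(cell_ids)}
        for c in det_cells:
            counts[gidx[g], cpos[c]] = max(1, int(_nb(rng, cfg.coverage_decoy_count_mean, 0.1, 1)[0]))

    for g in MITO_GENES:
        counts[gidx[g]] = _nb(rng, cfg.mito_nb_mean, 0.2, n_cells)

    bg_means = np.exp(rng.normal(cfg.background_nb_mean_log, cfg.background_nb_sigma_log, n_bg))
    lowexpr = bg_cause == "background_lowexpr"
    bg_means[lowexpr] = np.minimum(bg_means[lowexpr], cfg.lowexpr_nb_mean)
    for g, m in zip(background, bg_means):
        counts[gidx[g]] = _nb(rng, m, 0.5, n_cells)

    # plant the mitochondrial failures: mito reads dominate the cell
    cpos = {c: j for j, c in enumerate(cell_ids)}
    for c, reason in qc_fail.items():
        if reason == "high_mitochondrial":
            j = cpos[c]
            non_mito_total = int(counts[:, j].sum() - counts[[gidx[g] for g in MITO_GENES], j].sum())
            counts[gidx[MITO_GENES[0]], j] = 3 * max(non_mito_total, 1)

    # alignment stats: failures strictly below 50, the rest comfortably above
    umap = {}
    for c in cell_ids:
        if qc_fail.get(c) == "low_unique_mapping":
            umap[c] = float(rng.uniform(20.0, 45.0))
        else:
            umap[c] = float(rng.uniform(60.0, 95.0))
    stats = AlignmentStats(unique_map_pct=umap)

    groups = {c: "CTC" for c in ctc_ids}
    groups.update({c: "control" for c in control_ids})
    cm = CountMatrix(counts, gene_ids, cell_ids, groups)
    truth = SimTruth(
        gene_classes=gene_classes,
        true_markers=markers,
        decoys=decoys,
        qc_fail_cells=qc_fail,
        ctc_cells=passing_ctcs,
        control_cells=control_ids,
    )
    return cm, stats, truth


def simulate_references(cfg: SimConfig, truth: SimTruth) -> tuple[BloodReference, GeneAnnotation]:
    """Blood reference and gene annotation consistent with the gene classes.

    True markers (and the expression/coverage decoys) are blood-negative,
    protein-coding, plasma-membrane. Each decoy violates exactly its own
    filter; background genes carry their assigned failure cause.
    Deterministic for a given config+truth (seeded off cfg.seed).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    pbmc: dict[str, float] = {}
    blood: dict[str, float] = {}
    ann_rows = []

    def add_ann(g, biotype, locations):
        ann_rows.append({"gene_id": g, "symbol": g, "biotype": biotype, "locations": locations})

    for g, cls in truth.gene_classes.items():
        if cls in ("true_marker", "decoy_expression", "decoy_coverage"):
            pbmc[g] = 0.0
            blood[g] = float(rng.uniform(0.0, 10.0))
            add_ann(g, "protein_coding", frozenset({"plasma_membrane", "cytosol"}))
        elif cls == "decoy_pbmc":
            pbmc[g] = float(rng.uniform(0.5, 50.0))
            blood[g] = float(rng.uniform(0.0, 10.0))
            add_ann(g, "protein_coding", frozenset({"plasma_membrane"}))
        elif cls == "decoy_blood":
            pbmc[g] = 0.0
            blood[g] = float(rng.uniform(15.0, 100.0) + 1e-6)
            add_ann(g, "protein_coding", frozenset({"plasma_membrane"}))
        elif cls == "decoy_biotype":
            pbmc[g] = 0.0
            blood[g] = float(rng.uniform(0.0, 10.0))
            add_ann(g, "lincRNA", frozenset({"plasma_membrane"}))
        elif cls == "decoy_location":
            pbmc[g] = 0.0
            blood[g] = float(rng.uniform(0.0, 10.0))
            add_ann(g, "protein_coding", frozenset({"nucleoplasm", "cytosol"}))
        elif cls == "mito":
            pbmc[g] = float(rng.uniform(1.0, 100.0))  # mitochondrial genes are ubiquitous
            blood[g] = float(rng.uniform(50.0, 500.0))
            add_ann(g, "protein_coding", frozenset({"mitochondria"}))
        elif cls == "background_pbmc":
            pbmc[g] = float(rng.uniform(0.5, 200.0))
            blood[g] = float(rng.uniform(0.0, 200.0))
            add_ann(g, *_random_annotation(rng))
        elif cls == "background_blood":
            pbmc[g] = 0.0
            blood[g] = float(rng.uniform(15.0, 300.0) + 1e-6)
            add_ann(g, *_random_annotation(rng))
        elif cls == "background_lowexpr":
            pbmc[g] = 0.0
            blood[g] = float(rng.uniform(0.0, 10.0))
            add_ann(g, *_random_annotation(rng))
        else:
            raise ValueError(f"unknown gene class {cls!r} for {g}")

    ann_df = pd.DataFrame(ann_rows).set_index("gene_id")
    return BloodReference(pbmc, blood), GeneAnnotation(ann_df[["symbol", "biotype", "locations"]])


def _random_annotation(rng: np.random.Generator):
    biotype = "protein_coding" if rng.random() < 0.75 else str(rng.choice(["lincRNA", "pseudogene", "miRNA"]))
    locs = set()
    for loc, p in (("plasma_membrane", 0.3), ("cytosol", 0.5), ("nucleoplasm", 0.4)):
        if rng.random() < p:
            locs.add(loc)
    return biotype, frozenset(locs)


def check_truth_consistency(
    ref: BloodReference, ann: GeneAnnotation, truth: SimTruth, blood_expr_max: float = 15.0
) -> None:
    """Validate that emitted reference tables honor the class contracts."""
    for g, cls in truth.gene_classes.items():
        p, b = ref.lookup(g)
        if cls == "true_marker":
            assert p == 0 and b <= blood_expr_max, f"{g}: true marker blood-positive"
            assert ann.biotype(g) == "protein_coding" and "plasma_membrane" in ann.locations(g)
        elif cls == "decoy_pbmc":
            assert p > 0, f"{g}: decoy_pbmc has zero PBMC count"
        elif cls == "decoy_blood":
            assert b > blood_expr_max, f"{g}: decoy_blood within blood cap"
        elif cls == "decoy_biotype":
            assert ann.biotype(g) != "protein_coding", f"{g}: decoy_biotype is coding"
        elif cls == "decoy_location":
            assert "plasma_membrane" not in ann.locations(g), f"{g}: decoy_location on membrane"


# ---------------------------------------------------------------------------
# images and flow events


@dataclasses.dataclass(frozen=True)
class ImageSimConfig:
    """Disk-cell image generator parameters.

    Cells are non-overlapping disks on a jittered grid; the nuclear channel
    is bright inside every disk, the tag / cd45 / marker channels are
    bright or dim per planted class with >=5x separation between positive
    and negative levels. ``marker_positive_frac`` of the CTC-class cells
    are marker-bright; exactly ``round(frac * n_ctc)`` cells are planted,
    so the realized fraction is exact at zero noise.
    """

    n_ctc: int = 20
    n_immune: int = 80
    marker_positive_frac: float = 0.7
    immune_marker_positive_frac: float = 0.0
    cell_radius: int = 4
    spacing: int = 14
    shape: tuple[int, int] = (256, 256)
    level_high: float = 200.0
    level_low: float = 10.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.marker_positive_frac <= 1.0):
            raise ValueError("marker_positive_frac must lie in [0, 1]")
        if self.level_high < 5 * self.level_low:
            raise ValueError("positive/negative intensity separation must be >= 5x")


@dataclasses.dataclass
class ImageTruth:
    """Per-cell planted class and marker positivity, keyed by centroid."""

    table: pd.DataFrame  # columns: row, col, cell_class, marker_positive
    marker_positive_frac: float  # realized fraction among ctc-class cells


def simulate_if_image(cfg: ImageSimConfig = ImageSimConfig()) -> tuple[ImageStack, ImageTruth]:
    """Render a multi-channel image of disk-like cells with planted classes."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_ctc + cfg.n_immune
    rows = np.arange(cfg.spacing // 2, cfg.shape[0] - cfg.spacing // 2, cfg.spacing)
    cols = np.arange(cfg.spacing // 2, cfg.shape[1] - cfg.spacing // 2, cfg.spacing)
    sites = [(r, c) for r in rows for c in cols]
    if len(sites) < n:
        raise ValueError(f"canvas {cfg.shape} fits {len(sites)} cells at spacing {cfg.spacing}, need {n}")
    chosen = [sites[i] for i in rng.choice(len(sites), size=n, replace=False)]

    classes = ["ctc"] * cfg.n_ctc + ["immune"] * cfg.n_immune
    n_pos_ctc = int(round(cfg.marker_positive_frac * cfg.n_ctc))
    n_pos_imm = int(round(cfg.immune_marker_positive_frac * cfg.n_immune))
    marker_pos = [i < n_pos_ctc for i in range(cfg.n_ctc)] + [i < n_pos_imm for i in range(cfg.n_immune)]
    order = rng.permutation(n)

    channels = {ch: np.full(cfg.shape, cfg.level_low * 0.1) for ch in ("nuclear", "tag", "cd45", "marker")}
    yy, xx = np.mgrid[0 : cfg.shape[0], 0 : cfg.shape[1]]
    records = []
    for i in order:
        r, c = chosen[i]
        disk = (yy - r) ** 2 + (xx - c) ** 2 <= cfg.cell_radius**2
        cls = classes[i]
        channels["nuclear"][disk] = cfg.level_high
        channels["tag"][disk] = cfg.level_high if cls == "ctc" else cfg.level_low
        channels["cd45"][disk] = cfg.level_high if cls == "immune" else cfg.level_low
        channels["marker"][disk] = cfg.level_high if marker_pos[i] else cfg.level_low
        records.append({"row": r, "col": c, "cell_class": cls, "marker_positive": bool(marker_pos[i])})
    if cfg.noise_sigma > 0:
        for ch in channels:
            channels[ch] = np.clip(channels[ch] + rng.normal(0, cfg.noise_sigma, cfg.shape), 0, None)
    truth = ImageTruth(
        table=pd.DataFrame(records),
        marker_positive_frac=n_pos_ctc / cfg.n_ctc if cfg.n_ctc else float("nan"),
    )
    return ImageStack(channels), truth


@dataclasses.dataclass(frozen=True)
class FlowSimConfig:
    """Flow-event generator: a tag+/cd45- gated population with a planted
    marker-positive fraction (exact count ``round(frac * n_gated)``), plus
    off-gate events."""

    n_gated: int = 250
    n_other: int = 250
    marker_positive_frac: float = 0.4
    level_high: float = 1000.0
    level_low: float = 10.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.marker_positive_frac <= 1.0):
            raise ValueError("marker_positive_frac must lie in [0, 1]")


@dataclasses.dataclass
class FlowTruth:
    n_gated: int
    marker_positive_frac: float  # realized among gated events


def simulate_flow_events(cfg: FlowSimConfig = FlowSimConfig()) -> tuple[EventTable, FlowTruth]:
    """Draw per-event channel intensities with planted gate membership."""
    rng = np.random.default_rng(cfg.seed)
    n_pos = int(round(cfg.marker_positive_frac * cfg.n_gated))
    rows = []
    for i in range(cfg.n_gated):
        rows.append(
            {
                "tag": cfg.level_high,
                "cd45": cfg.level_low,
                "marker": cfg.level_high if i < n_pos else cfg.level_low,
            }
        )
    for _ in range(cfg.n_other):
        # off-gate: immune events (cd45 high) or double-negative debris
        if rng.random() < 0.8:
            rows.append({"tag": cfg.level_low, "cd45": cfg.level_high, "marker": cfg.level_low})
        else:
            rows.append({"tag": cfg.level_low, "cd45": cfg.level_low, "marker": cfg.level_low})
    df = pd.DataFrame(rows)
    if cfg.noise_sigma > 0:
        for ch in ("tag", "cd45", "marker"):
            df[ch] = np.clip(df[ch] + rng.normal(0, cfg.noise_sigma, len(df)), 0, None)
    df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    df.insert(0, "event_id", [f"ev{i}" for i in range(len(df))])
    truth = FlowTruth(
        n_gated=cfg.n_gated,
        marker_positive_frac=n_pos / cfg.n_gated if cfg.n_gated else float("nan"),
    )
    return EventTable(df), truth


@dataclasses.dataclass
class StudyBundle:
    """A complete coherent synthetic input set for the full screen."""

    counts: CountMatrix
    stats: AlignmentStats
    blood_ref: BloodReference
    annotation: GeneAnnotation
    truth: SimTruth


def simulate_full_study(cfg: SimConfig = SimConfig()) -> StudyBundle:
    """Counts + alignment stats + references + annotation, mutually consistent."""
    counts, stats, truth = simulate_ctc_counts(cfg)
    ref, ann = simulate_references(cfg, truth)
    check_truth_consistency(ref, ann, truth)
    return StudyBundle(counts=counts, stats=stats, blood_ref=ref, annotation=ann, truth=truth)
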