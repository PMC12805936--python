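# Methods

## Scope and data model

The package operates on a gene-by-cell integer count matrix (`CountMatrix`)
with cell groups (CTC vs. cultured control), a per-cell alignment-quality
table, a per-gene annotation table (biotype, subcellular locations) and a
per-gene blood reference (maximum single-cell PBMC count; whole-blood
expression in TPM-like units). Gene symbols are the join key everywhere;
matching is exact and case-sensitive, with an opt-in case-insensitive mode
on the readers (`casefold=True`) for references whose key handling is
unknown. A gene absent from the blood reference is treated as blood-silent
(0, 0); a gene absent from the annotation fails the biotype and location
filters. The asymmetry is deliberate and follows each filter's direction of
risk: unknown blood expression should not disqualify a candidate the
screen exists to find, but an unknown biotype/location must not pass a
filter whose entire purpose is positive evidence of a surface protein.
Both cases are logged.

## Quality control

Per cell we compute the detected-gene count, the mitochondrial read
percentage (counts on genes whose symbols start `MT-`, overridable by
explicit list, as a share of total counts) and, where available, the
percent of uniquely mapped reads. Removal rules are strict inequalities —
`unique_map_pct < 50` or `mito_pct > 50` — so boundary cells are retained.
Cells with zero total counts are removed with their own reason; this
degenerate case has no natural mitochondrial fraction and would otherwise
poison normalization. The 1,000-features-per-cell minimum is computed and
reported as a flag only (it is expected to remove nothing on the cohorts
this pipeline targets); `strict_features=True` enforces it. Genes kept must
be expressed (count > 0) in at least 5 cells.

## Normalization

Size factors are the median-of-ratios estimator: per gene a geometric-mean
pseudo-reference `r_g`, per cell the median over genes of `k_gj / r_g`.
The median is taken on the ratio scale (not the log scale — the two differ
at even gene counts, where the log-scale median would be the geometric
mean of the middle pair). Two modes:

* **standard** — reference genes are those positive in every cell; errors
  out, naming the alternative, when none exists.
* **positive** (default) — per-gene geometric means over positive counts
  only, per-cell medians over that cell's positive genes. This is the
  sparse-data generalization single-cell matrices need; on an all-positive
  matrix it reduces exactly to the standard estimator.

Factors are rescaled to geometric mean 1 (tolerance 1e-10 in tests) so
normalized values are comparable across runs. The log transform is
`log2(x + 1)` with the pseudocount fixed at 1.

The cascade's "mean expression" statistic is the arithmetic mean of the
*linear* normalized values over the CTC subset. Averaging on the log scale
is available (`expression_scale="log2"`) because the threshold's scale is
genuinely ambiguous in this kind of protocol; linear is the default and
the synthetic generator's margins are built for it.

## The filter cascade

Stages run in a fixed order: expressed → PBMC-subtraction → whole-blood
subtraction → expression → coverage → protein-coding → plasma-membrane →
curation. All thresholds remove by strict inequality (PBMC count > 0,
blood expression > 15, mean expression < 8, detection fraction < 30%), so
values exactly at a boundary survive. Coverage compares the detected-cell
count against `frac × n` with a 1e-12 guard so that an exact 30% is kept
under floating-point arithmetic. Membership filters are per-gene
predicates, so the final surviving set (threshold mode) is invariant under
any reordering of them; the percentile-mode expression filter is the
documented exception since its cutoff depends on the input set. In
percentile mode the cutoff is the highest-interpolation 95th percentile
and all ties at the cutoff are retained, so the survivor count can exceed
5%. The expression filter precedes the coverage filter; with both in
threshold mode the order between them is immaterial, but the reported
per-stage counts depend on it.

Curation (published staining evidence, antibody availability) is a manual
step and enters as a user-supplied keep-list intersected with the
survivors; entries absent from the surviving set produce a warning, not an
error. Whitelisted known markers are appended to the final candidate list
flagged `known=True`.

## Panel detection statistics

A gene is detected in a cell when its **raw** count is ≥ 1
(`detection_min_count` configurable). Detection is deliberately defined on
raw counts: size-factor normalization preserves zeros, so the choice only
matters if a threshold above 1 is ever configured. Panel coverage counts
the cells detecting no panel member (`n_missed`); adding a marker can only
shrink it. Default panels: published = {EPCAM, HER2, EGFR}, new =
{AHNAK2, CAVIN1, ODR4, TRIML2}, total = their union.

## Image quantification

Segmentation thresholds the nuclear channel (fixed cutoff, or Otsu as a
convenience), labels connected components (8-connectivity default) and
drops objects below `min_area` (default 20 px). Touching nuclei are not
split — the procedure mirrors a mask-plus-connected-components macro, and
the synthetic generator places non-overlapping cells; overlap handling is
out of scope. No mask dilation is applied by default; a
`dilation_radius` parameter exists for capturing membrane signal around
nuclei.

Per cell and channel we record the mean gray value. Positivity is
`mean ≥ cutoff`, with cutoffs uniform across all images of a batch. Cells
satisfying exactly one classification rule get that class; cells
satisfying none or several (e.g. tag⁺/CD45⁺ double positives) are
`ambiguous` and excluded from population denominators — an ambiguous cell
is neither an "unambiguously immune" cell nor a confident CTC.
Percent-positive is computed within a named population. Channels are
assumed registered (single-location multi-channel capture).

`gate_events` is the flow analog: a rectangular gate (per-channel
thresholds plus a positivity rule, default tag⁺/CD45⁻) selects the CTC
population, and the marker-positive fraction is computed inside it. An
empty gate yields an explicit `undefined` flag rather than a number.

## Synthetic data

The generators define the study conditions rather than mimic any real
dataset in detail:

* **Cohort**: 41 CTCs of which 3 fail the mapping filter and 1 the
  mitochondrial filter (37 survive) plus 6 control cells; 5,000 genes by
  default (configurable up to transcriptome scale), including 13 `MT-`
  genes. Counts are negative-binomial with class-specific means
  (variance = μ + αμ²); zeros arise from low means, with no separate
  dropout process, as appropriate for full-length single-cell chemistry.
* **Gene classes**: six `true_marker` genes (mean 30 counts, zero counts
  bumped to 1 so detection is certain even in tiny cohorts, blood-silent,
  protein-coding, plasma-membrane); one `decoy_<stage>` per cascade stage,
  each violating exactly its own filter with margin and clearing all
  others (e.g. the coverage decoy carries large counts in ~15% of cells:
  mean expression ≈ 16 but coverage < 30%); background genes each assigned
  a failure cause (55% PBMC-expressed, 10% blood-high, 35% low-expression)
  so that no background gene can reach the final candidate set. This makes
  planted-marker recovery an exact, not statistical, property and lets a
  cascade regression localize to one stage.
* **Images**: non-overlapping disks on a jittered grid; positive/negative
  channel levels 200/10 (20× separation; the generator enforces ≥ 5×);
  marker-positive CTC-class cells planted as an exact count
  `round(frac × n)`, so the realized fraction is recovered exactly at zero
  noise; optional additive Gaussian noise.
* **Flow events**: gated-population events with an exactly planted
  marker-positive count plus off-gate immune/debris events, shuffled.

Every generator is a pure function of its config and seed. What passing
tests therefore show is that the *rules* are implemented exactly; they do
not show robustness to features the generators omit — gene–gene
correlation, batch effects, ambient RNA, autofluorescence, overlapping
cells, or reference-version drift in the blood tables. With real
references the cascade's stage counts depend entirely on the reference
snapshots supplied.

## Problem sizes and numerics

The test suite and the acceptance script run the full screen at 5,000
genes (the package's chosen standard problem size; invariant sweeps use
120–800 genes × up to 100 replicates), images up to 1,050 cells on a
500×500 canvas, and event tables of a few hundred events. Size-factor
agreement with the brute-force oracle is asserted to 1e-10; boundary
guards use 1e-12; all reported fractions are exact ratios of integer
counts.

## Known limitations

* The cascade's real-data stage counts are reproducible only with the
  original versioned blood/annotation reference snapshots, which this
  package does not ship or download.
* No doublet detection, ambient-RNA correction, watershed splitting,
  illumination correction or spectral compensation.
* The percentile ("top 5%") expression mode and the ≥ 8 threshold mode
  disagree in general; the threshold mode is the operative default.
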