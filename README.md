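# ctcmarkers

Surface-marker screening for **live circulating tumor cells (CTCs)**.

Circulating tumor cells are rare cancer cells shed into the bloodstream.
Capturing them *alive* — for high-quality single-cell RNA sequencing —
requires staining cell-surface proteins, but the classic epithelial markers
(EpCAM, HER2, EGFR) miss mesenchymal tumor cells such as those of
triple-negative breast cancer. `ctcmarkers` implements the computational
screen that nominates new surface markers from CTC single-cell RNA-seq, and
the quantification rules used to validate marker cocktails by
immunofluorescence (IF) and flow cytometry.

The package is aimed at computational biologists running or auditing a
marker screen: every stage is a library function, there is a CLI
(`ctc-marker-screen`) over the same functions, and a seeded synthetic-data
module generates complete input bundles with ground truth so the whole
pipeline runs offline.

## The screen

1. **Cell QC.** Cells with < 50% uniquely mapped reads or > 50%
   mitochondrial reads are removed (strict inequalities — a cell at exactly
   50% passes). Genes expressed in fewer than 5 cells are dropped; a
   1,000-feature-per-cell minimum is computed as a flag.
2. **Normalization.** Median-of-ratios size factors
   `s_j = median_g (k_gj / r_g)` with `r_g` the gene's geometric-mean
   pseudo-reference, rescaled to geometric mean 1; expression is `x = k/s`
   and `y = log2(x + 1)`. A positive-counts mode handles sparse single-cell
   matrices where no gene is positive in every cell.
3. **Filter cascade.** From all genes expressed in CTCs, remove in order:
   genes with any PBMC single-cell expression (count > 0), genes with
   whole-blood expression > 15, genes with mean normalized CTC
   expression < 8 (or outside the top 5%, percentile mode), genes detected
   in < 30% of CTCs, non-protein-coding genes, genes not annotated to the
   plasma membrane, and genes outside a manually curated keep-list
   (antibody availability is not computable). Known markers (e.g. EGFR)
   can be whitelisted into the final panel.
4. **Panel statistics.** Per-marker detection fractions (raw count ≥ 1) and
   per-cocktail miss counts — how many cells no panel member detects.
5. **Validation quantification.** Nuclear-mask segmentation of
   multi-channel IF images, per-cell mean gray values, rule-based
   classification (CTC := tag⁺/CD45⁻, immune := CD45⁺/tag⁻, conflicts are
   ambiguous and excluded), percent-positive staining per population, and
   the flow-cytometry analog: rectangular gating of event tables.

## Worked example

```python
from ctcmarkers import SimConfig, simulate_full_study, RunConfig, run_full_screen

bundle = simulate_full_study(SimConfig(seed=1))   # 5,000 genes, 41 CTCs + 6 controls
report = run_full_screen(bundle.counts, bundle.stats,
                         bundle.blood_ref, bundle.annotation, RunConfig())
print(report.qc_summary["n_cells_kept"], "cells kept")
print(report.cascade.stage_counts)
print(report.candidate_genes)
```

prints

```
43 cells kept
{'expressed': 4971, 'pbmc_subtracted': 2224, 'blood_subtracted': 1728,
 'expression': 9, 'coverage': 8, 'protein_coding': 7,
 'plasma_membrane': 6, 'curated': 6}
['MARK1', 'MARK2', 'MARK3', 'MARK4', 'MARK5', 'MARK6']
```

Four of the 47 cells fail QC (three for low unique mapping, one for
mitochondrial fraction), leaving 37 CTCs and 6 controls. The cascade then
narrows 4,971 expressed genes to exactly the six planted true markers: each
decoy gene dies at the one stage it was built to violate (the counts drop
9 → 8 → 7 → 6 across the coverage, biotype and location filters).

The same run from the shell:

```bash
ctc-marker-screen simulate --preset full-study --seed 1 --out-dir bundle/
ctc-marker-screen run-all --bundle-dir bundle/ --out report.json
```

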