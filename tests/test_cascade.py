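import numpy as np
import pandas as pd
import pytest

from ctcmarkers.cascade import (
    CascadeConfig,
    apply_curation,
    drop_unexpressed,
    filter_by_coverage,
    filter_by_expression,
    filter_plasma_membrane,
    filter_protein_coding,
    run_cascade,
    subtract_pbmc_expressed,
    subtract_whole_blood,
)
from ctcmarkers.io import BloodReference, CountMatrix, GeneAnnotation
from ctcmarkers.simulate import SimConfig, simulate_full_study


def _ann(records):
    df = pd.DataFrame(
        {
            "symbol": [g for g, _, _ in records],
            "biotype": [b for _, b, _ in records],
            "locations": [frozenset(l) for _, _, l in records],
        },
        index=pd.Index([g for g, _, _ in records], name="gene_id"),
    )
    return GeneAnnotation(df)


class TestStageFilters:
    def test_drop_unexpressed(self):
        cm = CountMatrix(np.array([[0, 0], [1, 0]]), ["dead", "alive"], ["c1", "c2"])
        assert drop_unexpressed(cm) == {"alive"}

    def test_pbmc_boundary_strictly_above_zero_removed(self):
        ref = BloodReference({"a": 0.0001, "b": 0.0}, {})
        assert subtract_pbmc_expressed(frozenset("abc"), ref) == {"b", "c"}  # c absent -> kept

    def test_blood_boundary_15_kept(self):
        ref = BloodReference({}, {"a": 15.0, "b": 15.01})
        assert subtract_whole_blood(frozenset("ab"), ref) == {"a"}

    def test_expression_threshold_boundary(self):
        means = {"lo": 7.999, "hi": 8.0}
        assert filter_by_expression(frozenset(means), means) == {"hi"}

    def test_expression_percentile_distinct_means(self):
        means = {f"g{i}": float(i) for i in range(100)}
        cfg = CascadeConfig(expression_mode="percentile", top_pct=5.0)
        assert filter_by_expression(frozenset(means), means, cfg) == {f"g{i}" for i in range(95, 100)}

    def test_expression_percentile_ties_all_retained(self):
        # 10 genes tied at the cutoff: all survive, count exceeds 5% of 100
        means = {f"tie{i}": 50.0 for i in range(10)}
        means.update({f"lo{i}": i / 2.0 for i in range(90)})  # all strictly below 50
        cfg = CascadeConfig(expression_mode="percentile", top_pct=5.0)
        out = filter_by_expression(frozenset(means), means, cfg)
        assert out == {f"tie{i}" for i in range(10)}

    @pytest.mark.parametrize("n_detected,expected", [(11, False), (12, True)])
    def test_coverage_30pct_of_37(self, n_detected, expected):
        counts = np.zeros((1, 37), dtype=int)
        counts[0, :n_detected] = 3
        cm = CountMatrix(counts, ["g"], [f"c{i}" for i in range(37)])
        out = filter_by_coverage(frozenset(["g"]), cm)
        assert ("g" in out) is expected

    def test_coverage_exact_fraction_kept(self):
        counts = np.zeros((1, 10), dtype=int)
        counts[0, :3] = 1  # exactly 30%
        cm = CountMatrix(counts, ["g"], [f"c{i}" for i in range(10)])
        assert filter_by_coverage(frozenset(["g"]), cm) == {"g"}

    def test_biotype_and_location_membership(self):
        ann = _ann(
            [
                ("pc_pm", "protein_coding", {"plasma_membrane", "cytosol"}),
                ("pc_nuc", "protein_coding", {"nucleus"}),
                ("linc", "lincRNA", {"plasma_membrane"}),
                ("pc_none", "protein_coding", set()),
            ]
        )
        genes = frozenset(["pc_pm", "pc_nuc", "linc", "pc_none", "unannotated"])
        assert filter_protein_coding(genes, ann) == {"pc_pm", "pc_nuc", "pc_none"}
        assert filter_plasma_membrane(genes, ann) == {"pc_pm", "linc"}

    def test_curation_intersection_and_whitelist(self):
        kept, candidates = apply_curation(frozenset(["a", "b", "c"]), ["a", "b", "zzz"], whitelist=["EGFR"])
        assert kept == {"a", "b"}
        flags = {c["gene"]: c["known"] for c in candidates}
        assert flags == {"a": False, "b": False, "EGFR": True}

    def test_empty_curation_valid(self):
        kept, candidates = apply_curation(frozenset(["a"]), [])
        assert kept == frozenset() and candidates == []


class TestRunCascade:
    def test_planted_recovery(self):
        bundle = simulate_full_study(SimConfig(seed=7, n_genes=800))
        res = run_cascade(
            bundle.counts.subset(cells=bundle.truth.ctc_cells + bundle.truth.control_cells),
            bundle.blood_ref,
            bundle.annotation,
            cell_subset=bundle.truth.ctc_cells,
        )
        assert sorted(res.candidate_genes) == sorted(bundle.truth.true_markers)

    def test_each_decoy_dies_at_its_stage(self):
        bundle = simulate_full_study(SimConfig(seed=3, n_genes=800))
        res = run_cascade(
            bundle.counts.subset(cells=bundle.truth.ctc_cells),
            bundle.blood_ref,
            bundle.annotation,
            cell_subset=bundle.truth.ctc_cells,
        )
        stage_of = {st.name: st for st in res.stages}
        died_at = {}
        for stage, gene in bundle.truth.decoys.items():
            for st in res.stages:
                if gene in st.input_genes and gene not in st.surviving:
                    died_at[stage] = st.name
        assert died_at == {
            "pbmc": "pbmc_subtracted",
            "blood": "blood_subtracted",
            "expression": "expression",
            "coverage": "coverage",
            "biotype": "protein_coding",
            "location": "plasma_membrane",
        }
        assert all(stage_of[s].count >= 1 for s in stage_of)

    def test_nesting_and_weakly_decreasing_counts(self, rng):
        for trial in range(20):
            bundle = simulate_full_study(SimConfig(seed=int(rng.integers(2**31)), n_genes=300))
            res = run_cascade(
                bundle.counts.subset(cells=bundle.truth.ctc_cells),
                bundle.blood_ref,
                bundle.annotation,
                cell_subset=bundle.truth.ctc_cells,
            )
            res.validate_nesting()
            counts = [len(res.stages[0].input_genes)] + [st.count for st in res.stages]
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_membership_filter_permutation_invariance(self, rng):
        # threshold mode: the final surviving set is a pure intersection of
        # per-gene predicates, so filter order cannot matter
        import itertools

        from ctcmarkers.normalization import mean_normalized_expression, normalize_log2, size_factors

        bundle = simulate_full_study(SimConfig(seed=11, n_genes=200))
        cm = bundle.counts.subset(cells=bundle.truth.ctc_cells)
        cfg = CascadeConfig()
        norm = normalize_log2(cm, size_factors(cm, "positive"))
        means = mean_normalized_expression(norm)
        filters = {
            "pbmc": lambda g: subtract_pbmc_expressed(g, bundle.blood_ref),
            "blood": lambda g: subtract_whole_blood(g, bundle.blood_ref),
            "expr": lambda g: filter_by_expression(g, means, cfg),
            "cov": lambda g: filter_by_coverage(g, cm, None, cfg),
            "coding": lambda g: filter_protein_coding(g, bundle.annotation),
            "membrane": lambda g: filter_plasma_membrane(g, bundle.annotation),
        }
        start = drop_unexpressed(cm)
        reference = None
        names = list(filters)
        for perm in itertools.islice(itertools.permutations(names), 0, 720, 97):
            g = start
            for name in perm:
                g = filters[name](g)
            if reference is None:
                reference = g
            assert g == reference

    def test_tightening_threshold_never_increases_counts(self):
        bundle = simulate_full_study(SimConfig(seed=5, n_genes=400))
        cm = bundle.counts.subset(cells=bundle.truth.ctc_cells)
        loose = run_cascade(cm, bundle.blood_ref, bundle.annotation, CascadeConfig(min_mean_expr=4.0))
        tight = run_cascade(cm, bundle.blood_ref, bundle.annotation, CascadeConfig(min_mean_expr=12.0))
        for lo, hi in zip(tight.stages, loose.stages):
            assert lo.count <= hi.count

    def test_vacuous_thresholds_reduce_to_expressed_set(self):
        bundle = simulate_full_study(SimConfig(seed=2, n_genes=200))
        cm = bundle.counts.subset(cells=bundle.truth.ctc_cells)
        ann_all = _ann([(g, "protein_coding", {"plasma_membrane"}) for g in cm.gene_ids])
        cfg = CascadeConfig(
            pbmc_count_min_excl=1e12, blood_expr_max=1e12, min_mean_expr=0.0, min_detect_frac=0.0
        )
        res = run_cascade(cm, bundle.blood_ref, ann_all, cfg)
        assert frozenset(res.candidate_genes) == drop_unexpressed(cm)

    def test_stage_error_carries_stage_name(self):
        cm = CountMatrix(np.array([[1, 2]]), ["g"], ["c1", "c2"])
        with pytest.raises(RuntimeError, match="stage"):
            run_cascade(cm, BloodReference({}, {}), _ann([]), cell_subset=[])
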