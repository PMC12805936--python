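import numpy as np
import pandas as pd
import pytest

from ctcmarkers.imagequant import (
    DEFAULT_SCHEME,
    ClassScheme,
    GateConfig,
    SegmentationConfig,
    classify_cells,
    gate_events,
    measure_cells,
    percent_positive,
    segment_nuclei,
)
from ctcmarkers.io import EventTable, ImageStack
from ctcmarkers.simulate import FlowSimConfig, ImageSimConfig, simulate_flow_events, simulate_if_image

SEG = SegmentationConfig(nuclear_threshold=100.0, min_area=10)
CUT = 100.0  # positive/negative levels are 200/10, so one uniform cutoff works


def _quantify(image, population="ctc", marker_cutoff=CUT):
    mask = segment_nuclei(image, SEG)
    meas = measure_cells(mask, image)
    classes = classify_cells(meas, DEFAULT_SCHEME(CUT, CUT))
    return mask, meas, classes, percent_positive(meas, classes, population, "marker", marker_cutoff)


class TestSegmentNuclei:
    def test_blank_image_gives_zero_objects(self):
        image = ImageStack({"nuclear": np.zeros((32, 32))})
        assert segment_nuclei(image, SEG).max() == 0

    def test_five_disks_found(self):
        image, truth = simulate_if_image(ImageSimConfig(n_ctc=2, n_immune=3, shape=(96, 96), seed=1))
        mask = segment_nuclei(image, SEG)
        assert mask.max() == 5

    def test_min_area_boundary_discards_small(self):
        nuc = np.zeros((20, 20))
        nuc[2:5, 2:5] = 200.0  # 9 px object
        image = ImageStack({"nuclear": nuc})
        assert segment_nuclei(image, SegmentationConfig(nuclear_threshold=100, min_area=10)).max() == 0
        assert segment_nuclei(image, SegmentationConfig(nuclear_threshold=100, min_area=9)).max() == 1

    def test_missing_nuclear_channel_errors(self):
        with pytest.raises(ValueError):
            segment_nuclei(ImageStack({"tag": np.zeros((4, 4))}), SEG)


class TestMeasureCells:
    def test_uniform_channel_mean(self):
        nuc = np.zeros((10, 10))
        nuc[1:4, 1:4] = 200.0
        image = ImageStack({"nuclear": nuc, "marker": np.full((10, 10), 7.0)})
        meas = measure_cells(segment_nuclei(image, SegmentationConfig(100, min_area=4)), image)
        assert len(meas) == 1 and meas[0].mean_gray["marker"] == 7.0

    def test_mean_of_two_values(self):
        nuc = np.zeros((5, 5))
        nuc[2, 2:4] = 200.0
        marker = np.zeros((5, 5))
        marker[2, 2], marker[2, 3] = 10.0, 20.0
        image = ImageStack({"nuclear": nuc, "marker": marker})
        meas = measure_cells(segment_nuclei(image, SegmentationConfig(100, min_area=1)), image)
        assert meas[0].mean_gray["marker"] == pytest.approx(15.0)

    def test_empty_mask_and_shape_mismatch(self):
        image = ImageStack({"nuclear": np.zeros((6, 6))})
        assert measure_cells(np.zeros((6, 6), dtype=int), image) == []
        with pytest.raises(ValueError):
            measure_cells(np.zeros((4, 4), dtype=int), image)


class TestClassifyCells:
    def _meas(self, tag, cd45):
        from ctcmarkers.imagequant import CellMeasurement

        return CellMeasurement(1, 20, (0, 0), {"tag": tag, "cd45": cd45})

    @pytest.mark.parametrize(
        "tag,cd45,expected",
        [
            (200.0, 10.0, "ctc"),
            (10.0, 200.0, "immune"),
            (200.0, 200.0, "ambiguous"),  # double positive is excluded, not assigned
            (10.0, 10.0, "ambiguous"),
        ],
    )
    def test_rules(self, tag, cd45, expected):
        classes = classify_cells([self._meas(tag, cd45)], DEFAULT_SCHEME(CUT, CUT))
        assert classes[1] == expected

    def test_rule_with_missing_channel_errors(self):
        scheme = ClassScheme(cutoffs={"tag": 1, "cd45": 1, "panck": 1}, rules={"x": {"panck": True}})
        with pytest.raises(ValueError):
            classify_cells([self._meas(5, 5)], scheme)


class TestEndToEndImage:
    def test_generator_truth_reproduced_row_for_row(self):
        cfg = ImageSimConfig(n_ctc=20, n_immune=80, marker_positive_frac=0.7, seed=4)
        image, truth = simulate_if_image(cfg)
        mask, meas, classes, pct = _quantify(image)
        assert len(meas) == 100
        # match every measured cell to its planted truth row by centroid
        key = {(r.row, r.col): r for r in truth.table.itertuples()}
        for m in meas:
            t = key[(round(m.centroid[0]), round(m.centroid[1]))]
            assert classes[m.label] == t.cell_class
            assert (m.mean_gray["marker"] >= CUT) == t.marker_positive
        assert pct == pytest.approx(100 * truth.marker_positive_frac)

    def test_class_counts_partition_cells(self):
        image, _ = simulate_if_image(ImageSimConfig(seed=9, noise_sigma=5.0))
        mask, meas, classes, _ = _quantify(image)
        total = sum(
            sum(1 for v in classes.values() if v == c) for c in ("ctc", "immune", "ambiguous")
        )
        assert total == len(meas) == mask.max()

    def test_percent_positive_invariant_under_relabeling(self):
        image, _ = simulate_if_image(ImageSimConfig(seed=2))
        _, meas, classes, pct = _quantify(image)
        perm = list(reversed(meas))
        assert percent_positive(perm, classes, "ctc", "marker", CUT) == pct

    def test_empty_population_errors(self):
        image, _ = simulate_if_image(ImageSimConfig(n_ctc=1, n_immune=1, shape=(64, 64), seed=0))
        _, meas, classes, _ = _quantify(image)
        with pytest.raises(ValueError, match="panck"):
            percent_positive(meas, {m.label: "x" for m in meas}, "panck", "marker", CUT)

    @pytest.mark.parametrize("frac", [0.0, 0.4, 0.9, 1.0])
    def test_planted_fraction_recovered_exactly_without_noise(self, frac):
        image, truth = simulate_if_image(
            ImageSimConfig(n_ctc=30, n_immune=30, marker_positive_frac=frac, shape=(200, 200), seed=6)
        )
        _, _, _, pct = _quantify(image)
        assert pct == pytest.approx(100 * truth.marker_positive_frac)

    def test_noisy_recovery_within_two_points(self):
        cfg = ImageSimConfig(
            n_ctc=220, n_immune=30, marker_positive_frac=0.7, shape=(260, 260), noise_sigma=15.0, seed=8
        )
        image, truth = simulate_if_image(cfg)
        _, _, _, pct = _quantify(image)
        assert abs(pct - 100 * truth.marker_positive_frac) <= 2.0


class TestGateEvents:
    GATE = GateConfig(thresholds={"tag": 100.0, "cd45": 100.0}, marker_threshold=100.0)

    def test_all_bright_gated_fraction_one(self):
        df = pd.DataFrame({"event_id": ["a", "b"], "tag": [500.0, 500.0], "cd45": [1.0, 1.0], "marker": [500.0, 500.0]})
        res = gate_events(EventTable(df), self.GATE)
        assert res["n_gated"] == 2 and res["marker_positive_fraction"] == 1.0

    def test_planted_fraction_recovered(self):
        events, truth = simulate_flow_events(FlowSimConfig(n_gated=250, marker_positive_frac=0.4, seed=3))
        res = gate_events(events, self.GATE)
        assert res["n_gated"] == truth.n_gated == 250
        assert res["marker_positive_fraction"] == pytest.approx(truth.marker_positive_frac)
        assert res["marker_positive_fraction"] == pytest.approx(0.4)

    def test_high_planted_fraction_recovered(self):
        events, truth = simulate_flow_events(FlowSimConfig(n_gated=125, marker_positive_frac=0.952, seed=5))
        res = gate_events(events, self.GATE)
        assert res["marker_positive_fraction"] == pytest.approx(0.952)

    def test_empty_gate_flagged_undefined(self):
        df = pd.DataFrame({"event_id": ["a"], "tag": [1.0], "cd45": [500.0], "marker": [500.0]})
        res = gate_events(EventTable(df), self.GATE)
        assert res["undefined"] and res["marker_positive_fraction"] is None
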