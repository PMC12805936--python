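"""Immunofluorescence quantification and the flow-style gating analog.

The procedure mirrors a nuclear-mask ImageJ macro: the nuclear channel is
thresholded into a binary mask, connected components above a minimum area
become cells, and the mean gray value of every channel over each cell's
mask pixels is recorded. Boolean rules over per-channel positivity
(mean gray >= cutoff, cutoffs uniform across a batch) classify cells into
populations — e.g. CTCs are tag-positive/CD45-negative, unambiguous immune
cells are CD45-positive/tag-negative — and percent-positive staining is
computed within a population. Touching nuclei are not split (no watershed);
the synthetic generator places non-overlapping cells accordingly.

``gate_events`` applies the same logic to per-event intensity tables, the
flow-cytometry analog: a rectangular gate selects the CTC population and
the marker-positive fraction is computed within it.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label

from .io import EventTable, ImageStack

__all__ = [
    "SegmentationConfig",
    "CellMeasurement",
    "ClassScheme",
    "GateConfig",
    "DEFAULT_SCHEME",
    "segment_nuclei",
    "measure_cells",
    "classify_cells",
    "percent_positive",
    "gate_events",
]


@dataclasses.dataclass(frozen=True)
class SegmentationConfig:
    """Nuclear-mask segmentation parameters.

    nuclear_threshold : absolute intensity cutoff, or the string "otsu" to
        derive it from the nuclear channel's histogram.
    min_area : smallest object (pixels) kept as a cell.
    connectivity : 4 or 8 pixel neighbourhood.
    dilation_radius : optional mask dilation (pixels) to capture membrane
        signal around nuclei; default 0 (none).
    """

    nuclear_threshold: float | str = "otsu"
    min_area: int = 20
    connectivity: int = 8
    dilation_radius: int = 0

    def __post_init__(self) -> None:
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclasses.dataclass
class CellMeasurement:
    """One segmented cell: label, area, centroid, per-channel mean gray value."""

    label: int
    area: int
    centroid: tuple[float, float]
    mean_gray: dict[str, float]


@dataclasses.dataclass(frozen=True)
class ClassScheme:
    """Cutoffs per channel plus named boolean positivity rules.

    ``rules`` maps a class name to requirements like
    ``{"tag": True, "cd45": False}`` (tag-positive AND cd45-negative).
    A cell satisfying exactly one rule receives that class; cells
    satisfying none, or more than one, are ``ambiguous`` and excluded
    from population denominators.
    """

    cutoffs: Mapping[str, float]
    rules: Mapping[str, Mapping[str, bool]]

    def __post_init__(self) -> None:
        for name, rule in self.rules.items():
            missing = set(rule) - set(self.cutoffs)
            if missing:
                raise ValueError(f"rule {name!r} references channels without cutoffs: {sorted(missing)}")


DEFAULT_SCHEME_RULES = {
    "ctc": {"tag": True, "cd45": False},
    "immune": {"cd45": True, "tag": False},
}


def DEFAULT_SCHEME(tag_cutoff: float, cd45_cutoff: float) -> ClassScheme:
    """The CTC/immune scheme: ctc := tag+ cd45-; immune := cd45+ tag-."""
    return ClassScheme(cutoffs={"tag": tag_cutoff, "cd45": cd45_cutoff}, rules=DEFAULT_SCHEME_RULES)


@dataclasses.dataclass(frozen=True)
class GateConfig:
    """Rectangular event gate plus marker positivity threshold.

    ``population_rule`` mirrors ClassScheme rules: channel -> required
    positivity, with positivity meaning intensity >= the channel threshold.
    """

    thresholds: Mapping[str, float]
    population_rule: Mapping[str, bool] = dataclasses.field(
        default_factory=lambda: {"tag": True, "cd45": False}
    )
    marker_threshold: float = 0.0

    def __post_init__(self) -> None:
        for ch, t in self.thresholds.items():
            if not np.isfinite(t):
                raise ValueError(f"threshold for {ch!r} must be finite")


def segment_nuclei(image: ImageStack, cfg: SegmentationConfig = SegmentationConfig()) -> np.ndarray:
    """Label connected components of the thresholded nuclear channel.

    Components with area below ``min_area`` are discarded; survivors are
    relabeled 1..n with background 0.
    """
    if "nuclear" not in image:
        raise ValueError("image stack has no 'nuclear' channel")
    nuc = image["nuclear"]
    if cfg.nuclear_threshold == "otsu":
        thr = float(threshold_otsu(nuc))
    else:
        thr = float(cfg.nuclear_threshold)
    mask = nuc >= thr
    if cfg.dilation_radius > 0:
        mask = ndi.binary_dilation(mask, iterations=cfg.dilation_radius)
    labels = sk_label(mask, connectivity=1 if cfg.connectivity == 4 else 2)
    if labels.max() == 0:
        return labels
    areas = np.bincount(labels.ravel())
    keep = np.flatnonzero(areas >= cfg.min_area)
    keep = keep[keep > 0]
    remap = np.zeros(labels.max() + 1, dtype=labels.dtype)
    remap[keep] = np.arange(1, keep.size + 1)
    return remap[labels]


def measure_cells(mask: np.ndarray, image: ImageStack) -> list[CellMeasurement]:
    """Per labeled cell, the mean intensity of every channel over its pixels."""
    if mask.shape != image.shape:
        raise ValueError(f"mask shape {mask.shape} differs from image shape {image.shape}")
    n = int(mask.max())
    if n == 0:
        return []
    labels = np.arange(1, n + 1)
    areas = ndi.sum_labels(np.ones_like(mask, dtype=float), mask, labels).astype(int)
    centroids = ndi.center_of_mass(np.ones_like(mask, dtype=float), mask, labels)
    means = {ch: ndi.mean(image[ch], mask, labels) for ch in image.channels}
    return [
        CellMeasurement(
            label=int(lab),
            area=int(areas[i]),
            centroid=(float(centroids[i][0]), float(centroids[i][1])),
            mean_gray={ch: float(means[ch][i]) for ch in means},
        )
        for i, lab in enumerate(labels)
    ]


def classify_cells(measurements: Sequence[CellMeasurement], scheme: ClassScheme) -> dict[int, str]:
    """Assign each cell the unique rule it satisfies, else ``ambiguous``.

    Positivity is mean gray >= the channel's cutoff. Cells matching no
    rule, or more than one, are ambiguous and are excluded from population
    denominators downstream.
    """
    for name, rule in scheme.rules.items():
        for ch in rule:
            if measurements and ch not in measurements[0].mean_gray:
                raise ValueError(f"rule {name!r} references channel {ch!r} absent from measurements")
    out: dict[int, str] = {}
    for m in measurements:
        matched = [
            name
            for name, rule in scheme.rules.items()
            if all((m.mean_gray[ch] >= scheme.cutoffs[ch]) == want for ch, want in rule.items())
        ]
        out[m.label] = matched[0] if len(matched) == 1 else "ambiguous"
    return out


def percent_positive(
    measurements: Sequence[CellMeasurement],
    classes: Mapping[int, str],
    population: str,
    marker_channel: str,
    cutoff: float,
) -> float:
    """Percent of population cells whose marker mean gray is >= cutoff."""
    pop = [m for m in measurements if classes.get(m.label) == population]
    if not pop:
        raise ValueError(f"population {population!r} is empty")
    n_pos = sum(1 for m in pop if m.mean_gray[marker_channel] >= cutoff)
    return 100.0 * n_pos / len(pop)


def gate_events(events: EventTable, cfg: GateConfig, marker_channel: str = "marker") -> dict:
    """Apply the rectangular gate and compute the gated marker-positive fraction.

    Returns a dict with ``n_events``, ``n_gated``, ``marker_positive_fraction``
    (None, with ``undefined=True``, when the gate is empty).
    """
    in_gate = np.ones(len(events), dtype=bool)
    for ch, want in cfg.population_rule.items():
        if ch not in cfg.thresholds:
            raise KeyError(f"population rule channel {ch!r} has no threshold")
        pos = events.intensities(ch) >= cfg.thresholds[ch]
        in_gate &= pos if want else ~pos
    n_gated = int(in_gate.sum())
    result = {"n_events": len(events), "n_gated": n_gated}
    if n_gated == 0:
        result["marker_positive_fraction"] = None
        result["undefined"] = True
        return result
    marker = events.intensities(marker_channel)[in_gate]
    result["marker_positive_fraction"] = float((marker >= cfg.marker_threshold).mean())
    result["undefined"] = False
    return result
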