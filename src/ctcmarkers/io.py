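"""Readers and writers for every external artifact the pipeline touches.

All downstream modules consume only the in-memory containers defined here:
:class:`CountMatrix` (genes x cells integer counts), :class:`GeneAnnotation`
(biotype and subcellular location per gene), :class:`BloodReference` (per-gene
blood-expression evidence used by the subtraction cascade),
:class:`AlignmentStats` (per-cell mapping quality), :class:`ImageStack`
(registered multi-channel images) and :class:`EventTable` (per-event channel
intensities for gating).

Gene symbols are the join key across counts, annotation and references;
matching is exact and case-sensitive by default. Readers that merge tables
offer an optional case-insensitive mode (``casefold=True``) which upper-cases
keys on both sides before joining.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountMatrix",
    "GeneAnnotation",
    "BloodReference",
    "AlignmentStats",
    "ImageStack",
    "EventTable",
    "FormatError",
    "ValidationError",
    "read_count_matrix",
    "write_count_matrix",
    "read_gene_annotation",
    "read_blood_reference",
    "read_alignment_stats",
    "read_image_stack",
    "read_event_table",
    "write_screen_report",
    "read_screen_report",
]

CHANNEL_NAMES = ("nuclear", "tag", "cd45", "marker", "panck")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Parsed content violates a container invariant."""


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dups = set(), set()
        for i in ids:
            (dups if i in seen else seen).add(i)
        raise ValidationError(f"duplicate {what} identifiers: {sorted(dups)[:5]}")
    return ids


@dataclasses.dataclass
class CountMatrix:
    """Integer gene-by-cell count matrix with identifier labels.

    Parameters
    ----------
    counts
        Dense ``(n_genes, n_cells)`` array of non-negative integers; the raw
        count of gene *g* in cell *j*.
    gene_ids, cell_ids
        Ordered, unique identifier lists matching the matrix dimensions.
    cell_groups
        Optional map ``cell_id -> group`` (e.g. ``"CTC"`` / ``"control"``).
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be 2-D (genes x cells)")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if np.issubdtype(self.counts.dtype, np.floating):
            if not np.all(np.isfinite(self.counts)):
                raise ValidationError("counts contain non-finite values")
            if not np.all(self.counts == np.round(self.counts)):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if self.counts.min(initial=0) < 0:
            raise ValidationError("counts must be non-negative")
        if self.cell_groups is not None:
            unknown = set(self.cell_groups) - set(self.cell_ids)
            if unknown:
                raise ValidationError(f"cell_groups refer to unknown cells: {sorted(unknown)[:5]}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene: {gene}") from None

    def cell_indices(self, cells: Iterable[str] | None = None) -> np.ndarray:
        """Column indices for a cell-id subset (all cells if None)."""
        if cells is None:
            return np.arange(self.n_cells)
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            return np.array([pos[c] for c in cells], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown cell: {e.args[0]}") from None

    def cells_in_group(self, group: str) -> list[str]:
        if self.cell_groups is None:
            raise ValueError("matrix carries no cell_groups")
        return [c for c in self.cell_ids if self.cell_groups.get(c) == group]

    def subset(self, genes: Iterable[str] | None = None, cells: Iterable[str] | None = None) -> "CountMatrix":
        genes = list(genes) if genes is not None else self.gene_ids
        cells = list(cells) if cells is not None else self.cell_ids
        gpos = {g: i for i, g in enumerate(self.gene_ids)}
        gi = np.array([gpos[g] for g in genes], dtype=int)
        ci = self.cell_indices(cells)
        groups = None
        if self.cell_groups is not None:
            groups = {c: self.cell_groups[c] for c in cells if c in self.cell_groups}
        return CountMatrix(self.counts[np.ix_(gi, ci)], genes, cells, groups)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.cell_ids)


@dataclasses.dataclass
class GeneAnnotation:
    """Per-gene biotype and subcellular-location labels."""

    table: pd.DataFrame  # index: gene_id; columns: symbol, biotype, locations (frozenset)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene_id in annotation: {dups[:5]}")
        if (self.table["biotype"].astype(str).str.len() == 0).any():
            raise ValidationError("empty biotype in annotation")

    def biotype(self, gene: str) -> str | None:
        if gene in self.table.index:
            return str(self.table.at[gene, "biotype"])
        return None

    def locations(self, gene: str) -> frozenset[str]:
        if gene in self.table.index:
            return self.table.at[gene, "locations"]
        return frozenset()

    def __contains__(self, gene: str) -> bool:
        return gene in self.table.index


@dataclasses.dataclass
class BloodReference:
    """Per-gene blood-expression evidence.

    ``pbmc_max_count`` is the maximum single-cell count of the gene across
    PBMC cell types; ``blood_expression`` is whole-blood expression in
    TPM-like units. A gene absent from the reference is treated as
    unexpressed in blood: lookups return ``(0, 0)``, never an error.
    """

    pbmc_max_count: dict[str, float]
    blood_expression: dict[str, float]

    def __post_init__(self) -> None:
        for name, d in (("pbmc_max_count", self.pbmc_max_count), ("blood_expression", self.blood_expression)):
            for g, v in d.items():
                if not np.isfinite(v) or v < 0:
                    raise ValidationError(f"{name}[{g}] = {v!r} must be finite and >= 0")

    def lookup(self, gene: str) -> tuple[float, float]:
        return self.pbmc_max_count.get(gene, 0.0), self.blood_expression.get(gene, 0.0)


@dataclasses.dataclass
class AlignmentStats:
    """Per-cell alignment quality: percent uniquely mapped reads."""

    unique_map_pct: dict[str, float]
    total_reads: dict[str, int] | None = None

    def __post_init__(self) -> None:
        for c, v in self.unique_map_pct.items():
            if not (0.0 <= v <= 100.0):
                raise ValidationError(f"unique_map_pct[{c}] = {v} outside [0, 100]")


@dataclasses.dataclass
class ImageStack:
    """Registered single-location multi-channel image.

    Channel names are drawn from ``{nuclear, tag, cd45, marker, panck}``;
    all channels share one pixel grid.
    """

    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = {name: np.asarray(a).shape for name, a in self.channels.items()}
        if not self.channels:
            raise ValidationError("ImageStack needs at least one channel")
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2:
                raise ValidationError(f"channel {name!r} is not 2-D")
            if not np.all(np.isfinite(arr)) or arr.min() < 0:
                raise ValidationError(f"channel {name!r} has negative or non-finite intensities")
            self.channels[name] = arr
        if len(set(shapes.values())) > 1:
            raise ValidationError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels


@dataclasses.dataclass
class EventTable:
    """Per-event channel intensities (flow-cytometry analog)."""

    table: pd.DataFrame  # columns: event_id + channel columns

    def __post_init__(self) -> None:
        num = self.table.select_dtypes(include=[np.number])
        if not np.all(np.isfinite(num.to_numpy(dtype=float, na_value=np.nan))):
            raise ValidationError("event table contains non-finite values")

    def intensities(self, channel: str) -> np.ndarray:
        if channel not in self.table.columns:
            raise KeyError(f"event table has no channel {channel!r}")
        return self.table[channel].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# readers / writers


def _read_ids(path: str | Path, what: str) -> list[str]:
    ids = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    return _check_unique(ids, what)


def read_count_matrix(
    matrix_path: str | Path,
    gene_path: str | Path,
    cell_path: str | Path,
    cell_groups: Mapping[str, str] | None = None,
) -> CountMatrix:
    """Read a count matrix (Matrix Market triplet or dense TSV) plus labels.

    Matrix Market files follow the single-cell exchange convention: 1-based
    triplet indices, genes as rows, cells as columns; entries absent from the
    file are zero. Dense TSV files carry one row per gene with no header.
    """
    matrix_path = Path(matrix_path)
    genes = _read_ids(gene_path, "gene")
    cells = _read_ids(cell_path, "cell")
    if matrix_path.suffix == ".mtx" or matrix_path.read_bytes()[:14] == b"%%MatrixMarket":
        try:
            mat = scipy.io.mmread(str(matrix_path))
        except Exception as e:  # malformed header/triplets
            raise FormatError(f"cannot parse Matrix Market file {matrix_path}: {e}") from e
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    else:
        try:
            dense = pd.read_csv(matrix_path, sep="\t", header=None).to_numpy()
        except ValueError as e:
            raise FormatError(f"cannot parse dense TSV {matrix_path}: {e}") from e
    if dense.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix {matrix_path} declares shape {dense.shape} but labels give "
            f"{len(genes)} genes x {len(cells)} cells"
        )
    return CountMatrix(dense, genes, cells, dict(cell_groups) if cell_groups else None)


def write_count_matrix(cm: CountMatrix, matrix_path: str | Path, gene_path: str | Path, cell_path: str | Path) -> None:
    """Write a CountMatrix as Matrix Market triplets plus label files."""
    scipy.io.mmwrite(str(matrix_path), scipy.sparse.coo_matrix(cm.counts))
    Path(gene_path).write_text("\n".join(cm.gene_ids) + "\n")
    Path(cell_path).write_text("\n".join(cm.cell_ids) + "\n")


def read_gene_annotation(path: str | Path, casefold: bool = False) -> GeneAnnotation:
    """Read a gene annotation TSV: gene_id, symbol, biotype, locations.

    ``locations`` is a semicolon-separated list; empty means no annotated
    location. Duplicate gene ids are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "symbol", "biotype", "locations"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"annotation {path} missing columns: {sorted(missing)}")
    if casefold:
        df["gene_id"] = df["gene_id"].str.upper()
    df["locations"] = df["locations"].map(
        lambda s: frozenset(x.strip() for x in s.split(";") if x.strip())
    )
    df = df.set_index("gene_id")
    return GeneAnnotation(df[["symbol", "biotype", "locations"]])


def _read_keyed_tsv(path: str | Path, value_col: str, casefold: bool) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "gene_id" not in df.columns or value_col not in df.columns:
        raise FormatError(f"{path} must have columns gene_id and {value_col}")
    if casefold:
        df["gene_id"] = df["gene_id"].str.upper()
    if df["gene_id"].duplicated().any():
        raise ValidationError(f"duplicate gene_id in {path}")
    out = {}
    for g, raw in zip(df["gene_id"], df[value_col]):
        try:
            out[g] = float(raw)
        except ValueError:
            # fail loudly: silent coercion to 0 would corrupt filter boundaries
            raise ValidationError(f"non-numeric {value_col} for {g!r} in {path}: {raw!r}") from None
    return out


def read_blood_reference(pbmc_path: str | Path, blood_path: str | Path, casefold: bool = False) -> BloodReference:
    """Merge the PBMC single-cell max-count table and whole-blood table.

    Each TSV is keyed by ``gene_id`` with value columns ``pbmc_max_count``
    and ``blood_expression`` respectively. Genes present in only one table
    get 0 for the other field.
    """
    return BloodReference(
        pbmc_max_count=_read_keyed_tsv(pbmc_path, "pbmc_max_count", casefold),
        blood_expression=_read_keyed_tsv(blood_path, "blood_expression", casefold),
    )


def read_alignment_stats(path: str | Path) -> AlignmentStats:
    """Read per-cell alignment stats TSV: cell_id, unique_map_pct[, total_reads]."""
    df = pd.read_csv(path, sep="\t")
    if "cell_id" not in df.columns or "unique_map_pct" not in df.columns:
        raise FormatError(f"{path} must have columns cell_id and unique_map_pct")
    pct = dict(zip(df["cell_id"].astype(str), df["unique_map_pct"].astype(float)))
    total = None
    if "total_reads" in df.columns:
        total = dict(zip(df["cell_id"].astype(str), df["total_reads"].astype(int)))
    return AlignmentStats(unique_map_pct=pct, total_reads=total)


def read_image_stack(manifest_path: str | Path) -> ImageStack:
    """Read a channel manifest (YAML: channel name -> image path) into an ImageStack.

    Paths are resolved relative to the manifest's directory. TIFF files are
    read with tifffile; ``.npy`` arrays with numpy.
    """
    import yaml

    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    if not isinstance(manifest, dict):
        raise FormatError(f"manifest {manifest_path} must map channel names to file paths")
    channels = {}
    for name, rel in manifest.items():
        p = Path(rel)
        if not p.is_absolute():
            p = manifest_path.parent / p
        if p.suffix == ".npy":
            channels[name] = np.load(p)
        else:
            import tifffile

            channels[name] = tifffile.imread(p)
    return ImageStack(channels)


def read_event_table(path: str | Path) -> EventTable:
    """Read a CSV event table (event_id plus per-channel intensity columns)."""
    df = pd.read_csv(path)
    if "event_id" not in df.columns:
        df.insert(0, "event_id", [f"ev{i}" for i in range(len(df))])
    return EventTable(df)


def write_screen_report(cascade_result, qc_summary: Mapping | None, path: str | Path) -> None:
    """Write a machine-readable JSON screen report.

    Contains per-stage names, counts, surviving gene lists, the thresholds
    used, and the QC summary; reading it back reproduces the cascade result
    exactly (stage order preserved).
    """
    payload = {
        "schema_version": 1,
        "stages": [
            {
                "name": st.name,
                "n_input": len(st.input_genes),
                "n_surviving": len(st.surviving),
                "surviving": sorted(st.surviving),
            }
            for st in cascade_result.stages
        ],
        "final_candidates": cascade_result.final_candidates,
        "known_markers": sorted(cascade_result.known_markers),
        "config": cascade_result.config_snapshot,
        "qc_summary": dict(qc_summary) if qc_summary else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")


def read_screen_report(path: str | Path) -> dict:
    """Read back a screen report written by :func:`write_screen_report`."""
    return json.loads(Path(path).read_text())
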