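"""Readers and writers for the standard formats the toolkit touches.

Count matrices (dense CSV/TSV and MatrixMarket MTX with features/barcodes
companions), GMT / two-column TSV relationship tables, cluster-assignment
tables, GTF gene loci and BED peak coordinates.

Coordinate conventions: BED is 0-based half-open; GTF is 1-based inclusive
and is kept that way in :class:`GeneLocusIndex`. All internal interval
logic (the atac module) converts to 0-based half-open at the boundary.
"""

from __future__ import annotations

import gzip
import io as _io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


def _check_unique(ids: Sequence[str], axis: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise FormatError(f"duplicate {axis} IDs: {sorted(set(dups))[:5]} ...")


@dataclass
class CountMatrix:
    """features x cells nonnegative count/expression container.

    Rows are features (genes or peaks), columns are cells. The universal
    expression container of the toolkit.
    """

    values: np.ndarray
    feature_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise FormatError("values must be 2-D (features x cells)")
        if self.values.shape != (len(self.feature_ids), len(self.cell_ids)):
            raise FormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.cell_ids)} cells"
            )
        if self.values.size and self.values.min() < 0:
            raise FormatError("negative entries in count matrix")
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.cell_ids, "cell")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.cell_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns])


@dataclass
class RelationshipTable:
    """Metafeature -> target-gene sets (TF/miRNA targets, gene modules)."""

    entries: dict[str, set[str]]

    def __post_init__(self) -> None:
        for mf, targets in self.entries.items():
            if not targets:
                raise FormatError(f"metafeature {mf!r} has an empty target set")

    @property
    def metafeature_ids(self) -> list[str]:
        return list(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, mf: str) -> set[str]:
        return self.entries[mf]


@dataclass
class ClusterAssignment:
    """cell_id -> cluster label; labels are opaque strings."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise FormatError("empty cluster assignment")

    @property
    def labels(self) -> list[str]:
        """Distinct labels in first-appearance order."""
        out: list[str] = []
        for lab in self.mapping.values():
            if lab not in out:
                out.append(lab)
        return out

    def cells_of(self, label: str) -> list[str]:
        return [c for c, lab in self.mapping.items() if lab == label]

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class GeneLocusIndex:
    """gene_id -> (chrom, start, end, strand); 1-based inclusive as in GTF."""

    loci: dict[str, tuple[str, int, int, str]]

    def __post_init__(self) -> None:
        for g, (chrom, start, end, strand) in self.loci.items():
            if start > end:
                raise FormatError(f"gene {g}: start {start} > end {end}")

    def __len__(self) -> int:
        return len(self.loci)

    def __getitem__(self, gene_id: str) -> tuple[str, int, int, str]:
        return self.loci[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.loci


@dataclass
class RegionSet:
    """Ordered peak coordinates, 0-based half-open."""

    regions: list[tuple[str, int, int]]
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.region_ids:
            self.region_ids = [f"r{i + 1}" for i in range(len(self.regions))]
        if len(self.region_ids) != len(self.regions):
            raise FormatError("region_ids length mismatch")
        _check_unique(self.region_ids, "region")
        for rid, (chrom, start, end) in zip(self.region_ids, self.regions):
            if start >= end:
                raise FormatError(f"region {rid}: start {start} >= end {end} (0-based half-open)")

    def __len__(self) -> int:
        return len(self.regions)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


def _open_text(path: str | os.PathLike):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(path: Path) -> str:
    name = path.name.lower().removesuffix(".gz")
    if name.endswith(".mtx") or path.is_dir():
        return "mtx"
    if name.endswith(".csv"):
        return "csv"
    return "tsv"


def _mtx_companions(path: Path) -> tuple[Path, Path, Path]:
    """Locate matrix/features/barcodes for an MTX input (file or directory)."""
    if path.is_dir():
        folder = path
        matrix = None
        for cand in ("matrix.mtx", "matrix.mtx.gz"):
            if (folder / cand).exists():
                matrix = folder / cand
                break
        if matrix is None:
            raise FileNotFoundError(f"no matrix.mtx(.gz) in {folder}")
    else:
        matrix = path
        folder = path.parent
    feats = bars = None
    for cand in ("features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz"):
        if (folder / cand).exists():
            feats = folder / cand
            break
    for cand in ("barcodes.tsv", "barcodes.tsv.gz"):
        if (folder / cand).exists():
            bars = folder / cand
            break
    if feats is None or bars is None:
        raise FileNotFoundError(f"features/barcodes companions not found next to {matrix}")
    return matrix, feats, bars


def _read_id_column(path: Path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_count_matrix(
    path: str | os.PathLike,
    format: str | None = None,
    transpose: bool = False,
) -> CountMatrix:
    """Read a features x cells count matrix.

    Parameters
    ----------
    path
        Dense CSV/TSV (header row = cell IDs, first column = feature IDs),
        an ``.mtx`` file with ``features.tsv``/``barcodes.tsv`` alongside,
        or a 10x-style directory containing all three.
    format
        ``csv``, ``tsv`` or ``mtx``; sniffed from the filename if omitted.
    transpose
        Set for dialects that store cells as rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _sniff_format(path)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        cm = CountMatrix.from_frame(df)
    elif fmt == "mtx":
        matrix, feats, bars = _mtx_companions(path)
        m = scipy.io.mmread(matrix)
        values = np.asarray(m.todense() if scipy.sparse.issparse(m) else m)
        feature_ids = _read_id_column(feats)
        cell_ids = _read_id_column(bars)
        if values.shape != (len(feature_ids), len(cell_ids)):
            raise FormatError(
                f"MTX is {values.shape[0]}x{values.shape[1]} but companions list "
                f"{len(feature_ids)} features and {len(cell_ids)} barcodes"
            )
        if np.allclose(values, np.round(values)):
            values = np.round(values).astype(np.int64)
        cm = CountMatrix(values, feature_ids, cell_ids)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if transpose:
        cm = CountMatrix(cm.values.T, cm.cell_ids, cm.feature_ids)
    return cm


def write_count_matrix(m: CountMatrix, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a count matrix as dense CSV/TSV or MTX + companions."""
    path = Path(path)
    fmt = format or _sniff_format(path)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        m.to_frame().to_csv(path, sep=sep)
    elif fmt == "mtx":
        values = m.values
        if np.issubdtype(values.dtype, np.integer):
            sp = scipy.sparse.coo_matrix(values, dtype=np.int64)
        else:
            sp = scipy.sparse.coo_matrix(values)
        scipy.io.mmwrite(str(path), sp)
        folder = path.parent
        (folder / "features.tsv").write_text("".join(f"{g}\n" for g in m.feature_ids))
        (folder / "barcodes.tsv").write_text("".join(f"{c}\n" for c in m.cell_ids))
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# relationship tables
# ---------------------------------------------------------------------------


def read_relationships(path: str | os.PathLike, format: str | None = None) -> RelationshipTable:
    """Read metafeature -> target sets from GMT or two-column TSV.

    GMT: ``metafeature<TAB>description<TAB>target1<TAB>target2...`` — the
    description field is ignored. tsv2col: one ``metafeature<TAB>gene`` pair
    per line; duplicates are deduplicated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("gmt" if path.name.lower().removesuffix(".gz").endswith(".gmt") else "tsv2col")
    entries: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if fmt == "gmt":
                if len(fields) < 3:
                    raise FormatError(f"{path}:{lineno}: GMT line has <3 fields (no targets)")
                mf, targets = fields[0], [t for t in fields[2:] if t]
                if not targets:
                    raise FormatError(f"{path}:{lineno}: metafeature {mf!r} has no targets")
                entries.setdefault(mf, set()).update(targets)
            elif fmt == "tsv2col":
                if len(fields) != 2 or not fields[0] or not fields[1]:
                    raise FormatError(f"{path}:{lineno}: expected metafeature<TAB>gene")
                entries.setdefault(fields[0], set()).add(fields[1])
            else:
                raise ValueError(f"unknown format {fmt!r}")
    if not entries:
        raise FormatError(f"{path}: no relationships parsed")
    return RelationshipTable(entries)


def write_gmt(rel: RelationshipTable, path: str | os.PathLike, description: str = "na") -> None:
    with open(path, "w") as fh:
        for mf, targets in rel.entries.items():
            fh.write("\t".join([mf, description, *sorted(targets)]) + "\n")


# ---------------------------------------------------------------------------
# cluster assignments
# ---------------------------------------------------------------------------


def read_cluster_assignment(path: str | os.PathLike) -> ClusterAssignment:
    """Two-column TSV ``cell_id<TAB>cluster_label``; labels kept as strings."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mapping: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected cell_id<TAB>label")
            cell, label = fields
            if cell in mapping and mapping[cell] != label:
                raise FormatError(
                    f"{path}:{lineno}: cell {cell!r} assigned to both "
                    f"{mapping[cell]!r} and {label!r}"
                )
            mapping[cell] = label
    return ClusterAssignment(mapping)


def write_cluster_assignment(assignment: ClusterAssignment, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for cell, label in assignment.mapping.items():
            fh.write(f"{cell}\t{label}\n")


# ---------------------------------------------------------------------------
# GTF gene loci
# ---------------------------------------------------------------------------


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    """Tolerates both `key "value";` and key=value attribute dialects."""
    out: dict[str, str] = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk and '"' not in chunk:
            key, _, val = chunk.partition("=")
        else:
            key, _, val = chunk.partition(" ")
        key, val = key.strip(), val.strip().strip('"')
        if key and val:
            out.setdefault(key, val)
    return out


def read_gtf_gene_loci(path: str | os.PathLike) -> GeneLocusIndex:
    """Extract gene loci from a GTF (optionally gzipped).

    Rows with feature type ``gene`` define a gene's locus directly; for
    genes that have no ``gene`` row the locus is min(start)..max(end) over
    all rows sharing the gene_id. Coordinates stay 1-based inclusive.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    gene_rows: dict[str, tuple[str, int, int, str]] = {}
    span_rows: dict[str, tuple[str, int, int, str]] = {}
    n_parsed = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise FormatError(f"{path}:{lineno}: expected >=9 tab-separated columns")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame = cols[:8]
            attrs = _parse_gtf_attributes(cols[8])
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                continue
            n_parsed += 1
            start, end = int(start_s), int(end_s)
            if strand not in ("+", "-"):
                strand = "."
            if feature == "gene":
                gene_rows[gene_id] = (chrom, start, end, strand)
            else:
                if gene_id in span_rows:
                    c0, s0, e0, st0 = span_rows[gene_id]
                    span_rows[gene_id] = (c0, min(s0, start), max(e0, end), st0)
                else:
                    span_rows[gene_id] = (chrom, start, end, strand)
    if n_parsed == 0:
        raise FormatError(f"{path}: no rows with a parseable gene_id attribute")
    loci = dict(span_rows)
    loci.update(gene_rows)  # explicit gene rows win
    return GeneLocusIndex(loci)


# ---------------------------------------------------------------------------
# BED regions
# ---------------------------------------------------------------------------


def read_bed_regions(path: str | os.PathLike) -> RegionSet:
    """BED3+ peaks, 0-based half-open; column 4 (if present) names regions."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    regions: list[tuple[str, int, int]] = []
    ids: list[str] = []
    with _open_text(path) as fh:
        lineno = 0
        for raw in fh:
            raw = raw.rstrip("\n")
            if not raw.strip() or raw.startswith(("#", "track", "browser")):
                continue
            lineno += 1
            cols = raw.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}: BED line {lineno} has <3 columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            if start >= end:
                raise FormatError(f"{path}: BED line {lineno}: start {start} >= end {end}")
            regions.append((chrom, start, end))
            ids.append(cols[3] if len(cols) >= 4 and cols[3] else f"r{lineno}")
    return RegionSet(regions, ids)


def write_bed_regions(rs: RegionSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rid, (chrom, start, end) in zip(rs.region_ids, rs.regions):
            fh.write(f"{chrom}\t{start}\t{end}\t{rid}\n")
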