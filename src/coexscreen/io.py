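"""Readers and writers for every on-disk format the pipeline touches.

Formats are deliberately plain text so runs are inspectable and diffable:

* bulk expression tables — TSV with a header row, either orientation;
* sparse single-cell counts — a directory with Matrix-Market triplets
  (``matrix.mtx``, cells x genes), ``features.tsv``, ``barcodes.tsv`` and an
  ``annotations.tsv`` mapping each cell to its group (cell type);
* module partitions — three-column TSV (group, gene_id, module_label);
* brightness-coded matrices — whitespace-delimited numeric rows with no
  header, the dialect ImageJ/Fiji accepts via File > Import > Text Image.

Readers never reorder genes or cells relative to the source files, and every
reader/writer pair round-trips exactly (up to float formatting for the text
image, which is lossy by design).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ParseError",
    "ConfigError",
    "DataError",
    "UNASSIGNED",
    "BulkExpressionTable",
    "SingleCellCounts",
    "ModulePartition",
    "read_bulk_table",
    "write_bulk_table",
    "read_sparse_counts",
    "write_sparse_counts",
    "write_text_image",
    "read_partition",
    "write_partition",
]


class ParseError(ValueError):
    """A file exists but its contents violate the declared dialect."""


class ConfigError(ValueError):
    """Invalid parameter combination supplied by the caller."""


class DataError(ValueError):
    """Structurally valid input that the requested operation cannot use."""


#: Reserved module label for genes not placed in any module.
UNASSIGNED = "unassigned"


def _check_unique(labels, what: str) -> None:
    seen = set()
    dups = []
    for x in labels:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ParseError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class BulkExpressionTable:
    """Nonnegative genes x samples expression matrix with labels.

    Values are platform expression units (microarray intensity or RPKM);
    the container enforces shape agreement, nonnegativity and finiteness.
    """

    gene_ids: list[str]
    sample_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_labels = [str(s) for s in self.sample_labels]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_labels, "sample label")
        if self.values.shape != (len(self.gene_ids), len(self.sample_labels)):
            raise ParseError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_labels)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ParseError("expression values must be finite")
        if np.any(self.values < 0):
            raise ParseError("expression values must be nonnegative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_labels)

    def row(self, gene_id: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene_id)
        except ValueError:
            raise DataError(f"gene {gene_id!r} not present in table") from None
        return self.values[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_labels)


@dataclass
class SingleCellCounts:
    """Sparse cells x genes nonnegative integer counts with cell-type labels."""

    cell_ids: list[str]
    gene_ids: list[str]
    counts: sp.csr_matrix
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        _check_unique(self.cell_ids, "cell id")
        _check_unique(self.gene_ids, "gene id")
        self.counts = sp.csr_matrix(self.counts)
        self.counts.eliminate_zeros()
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ParseError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if self.counts.nnz:
            data = self.counts.data
            if np.any(data < 0):
                raise ParseError("counts must be nonnegative")
            if not np.allclose(data, np.round(data)):
                raise ParseError("counts must be integral")
        missing = [c for c in self.cell_ids if c not in self.group_of]
        if missing:
            raise ParseError(f"cells without a group label: {missing[:5]}")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def groups(self) -> list[str]:
        """Group labels in first-appearance order over cells."""
        out: list[str] = []
        seen = set()
        for c in self.cell_ids:
            g = self.group_of[c]
            if g not in seen:
                seen.add(g)
                out.append(g)
        return out

    def subset_cells(self, keep: np.ndarray) -> "SingleCellCounts":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        cells = [self.cell_ids[i] for i in keep]
        return SingleCellCounts(
            cell_ids=cells,
            gene_ids=list(self.gene_ids),
            counts=self.counts[keep],
            group_of={c: self.group_of[c] for c in cells},
        )


@dataclass
class ModulePartition:
    """Per-group mapping gene -> module label; ``unassigned`` is reserved."""

    assignments: dict[str, dict[str, str]] = field(default_factory=dict)
    min_module_size: int | None = None

    def groups(self) -> list[str]:
        return list(self.assignments)

    def label(self, group: str, gene: str) -> str | None:
        return self.assignments.get(group, {}).get(gene)


# ---------------------------------------------------------------------------
# bulk tables


def read_bulk_table(path, orientation: str = "samples_as_rows") -> BulkExpressionTable:
    """Read a bulk expression TSV into genes x samples orientation.

    The public expression-atlas downloads list samples as rows, which is the
    default ``orientation``; pass ``"genes_as_rows"`` for matrices written the
    internal way round. Non-numeric cells and duplicated gene ids are errors.
    """
    if orientation not in ("samples_as_rows", "genes_as_rows"):
        raise ConfigError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.isnull().any() or df.columns.isnull().any():
        raise ParseError(f"{path}: empty row or column label")
    numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at row "
            f"{df.index[i]!r}, column {df.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: missing value at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if orientation == "samples_as_rows":
        numeric = numeric.T
    gene_ids = [str(g) for g in numeric.index]
    dup = pd.Index(gene_ids)[pd.Index(gene_ids).duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicated gene id(s): {sorted(set(dup))}")
    return BulkExpressionTable(
        gene_ids=gene_ids,
        sample_labels=[str(s) for s in numeric.columns],
        values=numeric.to_numpy(dtype=float),
    )


def write_bulk_table(table: BulkExpressionTable, path, orientation: str = "samples_as_rows") -> None:
    """Write a bulk table as TSV in the requested orientation."""
    if orientation not in ("samples_as_rows", "genes_as_rows"):
        raise ConfigError(f"unknown orientation {orientation!r}")
    df = table.to_frame()
    if orientation == "samples_as_rows":
        df = df.T
    df.index.name = "label"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# sparse counts


def read_sparse_counts(directory, permissive: bool = False) -> SingleCellCounts:
    """Read a sparse count directory (matrix.mtx + features/barcodes/annotations).

    ``matrix.mtx`` holds cells x genes coordinates; ``features.tsv`` and
    ``barcodes.tsv`` are one id per line; ``annotations.tsv`` has a header
    row ``cell_id<TAB>group``. Cells missing an annotation raise an error
    unless ``permissive`` is set, in which case they get group "unannotated".
    """
    d = Path(directory)
    mat = scipy.io.mmread(os.fspath(d / "matrix.mtx"))
    genes = (d / "features.tsv").read_text().split()
    cells = (d / "barcodes.tsv").read_text().split()
    if mat.shape != (len(cells), len(genes)):
        raise ParseError(
            f"{d}: matrix header {mat.shape} does not match "
            f"{len(cells)} barcodes x {len(genes)} features"
        )
    ann = pd.read_csv(d / "annotations.tsv", sep="\t", dtype=str)
    if list(ann.columns[:2]) != ["cell_id", "group"]:
        raise ParseError(f"{d}/annotations.tsv: expected columns cell_id, group")
    if ann["cell_id"].duplicated().any():
        dups = ann.loc[ann["cell_id"].duplicated(), "cell_id"].tolist()
        raise ParseError(f"{d}/annotations.tsv: duplicated cell id(s): {dups[:5]}")
    group_of = dict(zip(ann["cell_id"], ann["group"]))
    missing = [c for c in cells if c not in group_of]
    if missing and not permissive:
        raise ParseError(
            f"{d}/annotations.tsv: {len(missing)} cell(s) without annotation, "
            f"e.g. {missing[:5]} (pass permissive=True to label them 'unannotated')"
        )
    for c in missing:
        group_of[c] = "unannotated"
    counts = sp.csr_matrix(mat)
    return SingleCellCounts(
        cell_ids=cells,
        gene_ids=genes,
        counts=counts,
        group_of={c: group_of[c] for c in cells},
    )


def write_sparse_counts(counts: SingleCellCounts, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(os.fspath(d / "matrix.mtx"), sp.coo_matrix(counts.counts))
    (d / "features.tsv").write_text("\n".join(counts.gene_ids) + "\n")
    (d / "barcodes.tsv").write_text("\n".join(counts.cell_ids) + "\n")
    with open(d / "annotations.tsv", "w") as fh:
        fh.write("cell_id\tgroup\n")
        for c in counts.cell_ids:
            fh.write(f"{c}\t{counts.group_of[c]}\n")


# ---------------------------------------------------------------------------
# text image


def write_text_image(matrix, path) -> None:
    """Write a [0, 1] matrix as the plain text-image dialect ImageJ imports.

    One matrix row per line, values whitespace-separated, no header. Numbers
    are written with up to 6 significant digits. Values outside [0, 1] are an
    error: callers normalise (e.g. per-gene to the row maximum) first.
    """
    m = np.asarray(matrix, dtype=float)
    if m.size == 0:
        raise DataError("cannot write an empty text image")
    if m.ndim != 2:
        raise DataError(f"text image requires a 2-D matrix, got ndim={m.ndim}")
    if not np.all(np.isfinite(m)):
        raise DataError("text image values must be finite")
    if m.min() < 0 or m.max() > 1:
        raise DataError("text image values must lie in [0, 1]; normalise first")
    with open(path, "w") as fh:
        for row in m:
            fh.write(" ".join(format(v, ".6g") for v in row) + "\n")


# ---------------------------------------------------------------------------
# module partitions


def read_partition(path) -> ModulePartition:
    """Read a (group, gene_id, module_label) TSV into a ModulePartition."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["group", "gene_id", "module_label"]
    if list(df.columns[:3]) != expected:
        raise ParseError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    assignments: dict[str, dict[str, str]] = {}
    for grp, gene, label in df.itertuples(index=False):
        genes = assignments.setdefault(grp, {})
        if gene in genes:
            raise ParseError(f"{path}: gene {gene!r} appears twice in group {grp!r}")
        genes[gene] = label
    return ModulePartition(assignments=assignments)


def write_partition(partition: ModulePartition, path) -> None:
    with open(path, "w") as fh:
        fh.write("group\tgene_id\tmodule_label\n")
        for grp, genes in partition.assignments.items():
            for gene, label in genes.items():
                fh.write(f"{grp}\t{gene}\t{label}\n")
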