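"""Tabular I/O: count matrices, sample sheets and contig-to-gene maps.

All files are UTF-8, tab-separated, unquoted text.  A count matrix has one
row per gene (or per contig, pre-aggregation) and one column per sample;
the first header cell names the identifier column and the remaining header
cells are sample identifiers.  A sample sheet assigns each sequencing
sample to a cell line, a cell class (``fibroblast``, ``es`` or ``ips``)
and a replicate number.  A contig map has two columns, ``contig_id`` and
``gene_id``; counts of all contigs representing the same gene are summed
during aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CELL_CLASSES = ("fibroblast", "es", "ips")

SHEET_COLUMNS = ("sample_id", "line_id", "cell_class", "replicate")


class InputValidationError(ValueError):
    """A file or in-memory table violates the pipeline's input contract."""


@dataclass(frozen=True)
class CountMatrix:
    """Non-negative gene x sample count table.

    ``data`` is indexed by gene identifier with one column per sample.
    Values must be finite and non-negative; integrality is enforced at
    ingest time (see :func:`read_count_matrix`), while in-memory matrices
    may hold fractional values as emitted by bias-corrected counters.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise InputValidationError(f"duplicate gene id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise InputValidationError(f"duplicate sample id {dup!r}")
        values = df.to_numpy()
        if values.size and (not np.all(np.isfinite(values)) or (values < 0).any()):
            raise InputValidationError("counts must be finite and non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise InputValidationError(f"unknown sample ids: {missing}")
        return CountMatrix(self.data.loc[:, sample_ids])


@dataclass(frozen=True)
class SampleSheet:
    """Sample -> (line, cell class, replicate) assignment.

    Exactly one line must be of class ``fibroblast`` and at least one of
    class ``es``; every line needs >= 2 replicates, because within-line
    replication is what the dispersion estimator pools.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise InputValidationError(f"sample sheet missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise InputValidationError(f"duplicate sample id {dup!r}")
        bad = sorted(set(df["cell_class"]) - set(CELL_CLASSES))
        if bad:
            raise InputValidationError(
                f"unknown cell_class {bad}; allowed: {list(CELL_CLASSES)}"
            )
        reps = pd.to_numeric(df["replicate"], errors="coerce")
        if reps.isna().any() or (reps <= 0).any() or (reps != reps.astype(int)).any():
            raise InputValidationError("replicate must be a positive integer")
        fib = df.loc[df["cell_class"] == "fibroblast", "line_id"].unique()
        if len(fib) != 1:
            raise InputValidationError(
                f"need exactly one fibroblast line, found {len(fib)}"
            )
        if not (df["cell_class"] == "es").any():
            raise InputValidationError("need at least one es line")
        sizes = df.groupby("line_id").size()
        singles = sizes[sizes < 2].index.tolist()
        if singles:
            raise InputValidationError(
                f"lines with a single replicate (no within-group variance): {singles}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def fibroblast_line(self) -> str:
        return self.table.loc[self.table["cell_class"] == "fibroblast", "line_id"].iloc[0]

    @property
    def es_lines(self) -> list[str]:
        return list(dict.fromkeys(self.table.loc[self.table["cell_class"] == "es", "line_id"]))

    @property
    def ips_lines(self) -> list[str]:
        return list(dict.fromkeys(self.table.loc[self.table["cell_class"] == "ips", "line_id"]))

    def samples_of_line(self, line_id: str) -> list[str]:
        sel = self.table.loc[self.table["line_id"] == line_id, "sample_id"]
        if sel.empty:
            raise InputValidationError(f"unknown line id {line_id!r}")
        return list(sel)

    def line_of_sample(self) -> pd.Series:
        return self.table.set_index("sample_id")["line_id"]


@dataclass(frozen=True)
class ContigMap:
    """Many-to-one contig -> gene assignment."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table
        for col in ("contig_id", "gene_id"):
            if col not in df.columns:
                raise InputValidationError(f"contig map missing column {col!r}")
        if df["contig_id"].duplicated().any():
            dup = df.loc[df["contig_id"].duplicated(), "contig_id"].iloc[0]
            raise InputValidationError(f"contig {dup!r} mapped more than once")
        empty = df["gene_id"].astype(str).str.strip() == ""
        if empty.any():
            contig = df.loc[empty, "contig_id"].iloc[0]
            raise InputValidationError(f"contig {contig!r} mapped to an empty gene id")

    def as_series(self) -> pd.Series:
        return self.table.set_index("contig_id")["gene_id"]


def _split_rows(path) -> list[list[str]]:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n").split("\t") for line in fh if line.rstrip("\n")]


def read_count_matrix(path, allow_fractional: bool = False) -> CountMatrix:
    """Read a tab-separated gene x sample count matrix.

    Row and column order of the file are preserved.  Cells must parse as
    non-negative numbers; non-integer values are rejected unless
    ``allow_fractional`` is set (bias-corrected counters emit fractions).
    """
    rows = _split_rows(path)
    if not rows:
        raise InputValidationError(f"{path}: empty file")
    header = rows[0]
    ncol = len(header)
    if ncol < 2:
        raise InputValidationError(f"{path}: header must name >= 1 sample column")
    sample_ids = header[1:]
    gene_ids: list[str] = []
    values = np.empty((len(rows) - 1, ncol - 1), dtype=float)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != ncol:
            raise InputValidationError(
                f"{path}: line {i} has {len(row)} fields, expected {ncol}"
            )
        gene_ids.append(row[0])
        for j, cell in enumerate(row[1:], start=1):
            try:
                v = float(cell)
            except ValueError:
                raise InputValidationError(
                    f"{path}: non-numeric count at line {i}, column {header[j]!r}"
                ) from None
            if not np.isfinite(v) or v < 0:
                raise InputValidationError(
                    f"{path}: negative or non-finite count at line {i}, column {header[j]!r}"
                )
            if not allow_fractional and v != int(v):
                raise InputValidationError(
                    f"{path}: non-integer count {cell} at line {i}, column {header[j]!r}"
                    " (use allow_fractional for bias-corrected counts)"
                )
            values[i - 2, j - 1] = v
    if not allow_fractional:
        values = values.astype(np.int64)
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    return CountMatrix(df)


def write_count_matrix(matrix: CountMatrix, path) -> None:
    matrix.data.rename_axis("gene_id").to_csv(path, sep="\t")


def read_sample_sheet(path) -> SampleSheet:
    """Read a tab-separated sample sheet with the four named columns."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "line_id": str, "cell_class": str})
    return SampleSheet(df.reset_index(drop=True))


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def read_contig_map(path) -> ContigMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return ContigMap(df)


def check_samples_match(matrix: CountMatrix, sheet: SampleSheet) -> None:
    """Every sheet sample must appear in the matrix."""
    missing = sorted(set(sheet.sample_ids) - set(matrix.sample_ids))
    if missing:
        raise InputValidationError(f"sheet samples absent from count matrix: {missing}")


def aggregate_contigs(contig_counts: CountMatrix, contig_map: ContigMap) -> CountMatrix:
    """Sum counts of all contigs representing the same gene.

    Contigs absent from the map (unannotated assembly products) are
    dropped and the dropped fraction logged; sample order and per-sample
    totals over the mapped contigs are preserved.  Gene order follows the
    first occurrence of each gene among mapped contigs.
    """
    mapping = contig_map.as_series()
    present = contig_counts.data.index.isin(mapping.index)
    n_drop = int((~present).sum())
    if n_drop:
        logger.info(
            "dropping %d/%d unmapped contigs (%.1f%%)",
            n_drop, len(present), 100.0 * n_drop / len(present),
        )
    kept = contig_counts.data.loc[present]
    genes = mapping.reindex(kept.index)
    agg = kept.groupby(genes, sort=False).sum()
    agg.index.name = "gene_id"
    return CountMatrix(agg)
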