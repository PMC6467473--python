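"""Reading, writing and harmonizing expression data.

The on-disk dialect is deliberately plain: tab-separated text with genes as
rows (first column the gene identifier) and samples as columns, a companion
sample sheet with one row per sample, two-column TSV ortholog maps, and
standard GMT gene-set files. Gene identifiers are opaque strings; no
identifier-version munging is attempted.

Units are tracked explicitly (``counts``, ``fpkm``, ``log2fpkm``) so that
log transforms and filters cannot silently be applied twice or on the wrong
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, HarmonizationError, UnitError

UNITS = ("counts", "fpkm", "log2fpkm")

#: FPKM floor applied before any log transform, to keep logs finite.
FPKM_FLOOR = 1e-6

SAMPLE_SHEET_COLUMNS = ("dataset", "cell_line", "timepoint", "replicate")


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples abundance table with an explicit unit tag.

    ``values`` is a pandas DataFrame indexed by gene id with sample ids as
    columns. Counts and FPKM values must be non-negative and finite;
    log2fpkm values may be any finite real.
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self):
        if self.unit not in UNITS:
            raise UnitError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()].unique().tolist()[:5]
            raise FormatError(f"duplicate gene ids: {dup}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()].unique().tolist()[:5]
            raise FormatError(f"duplicate sample ids: {dup}")
        arr = v.to_numpy(dtype=float, copy=False) if v.size else np.empty((0, 0))
        if v.size and not np.isfinite(arr).all():
            raise FormatError("expression matrix contains missing or non-finite values")
        if self.unit in ("counts", "fpkm") and v.size and (arr < 0).any():
            raise FormatError(f"negative values are not valid for unit {self.unit!r}")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = set(genes) - set(self.values.index)
        if missing:
            raise KeyError(f"{len(missing)} requested genes absent from matrix")
        return replace(self, values=self.values.loc[list(genes)])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = set(samples) - set(self.values.columns)
        if missing:
            raise KeyError(f"{len(missing)} requested samples absent from matrix")
        return replace(self, values=self.values[list(samples)])


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample metadata: dataset, cell line, timepoint (or embryo stage),
    replicate. Indexed by sample id. Timepoint order is the order of first
    appearance, which the generators emit chronologically."""

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        if self.table.index.duplicated().any():
            raise FormatError("duplicate sample ids in sample sheet")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.table.index]

    def timepoints(self) -> list[str]:
        return list(dict.fromkeys(self.table["timepoint"].astype(str)))

    def cell_lines(self) -> list[str]:
        return list(dict.fromkeys(self.table["cell_line"].astype(str)))

    def samples_for(self, cell_line: str | None = None,
                    timepoint: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if cell_line is not None:
            mask &= self.table["cell_line"].astype(str) == str(cell_line)
        if timepoint is not None:
            mask &= self.table["timepoint"].astype(str) == str(timepoint)
        return [str(s) for s in self.table.index[mask]]

    def check_matches(self, matrix: ExpressionMatrix) -> None:
        if set(self.sample_ids) != set(matrix.sample_ids):
            only_sheet = sorted(set(self.sample_ids) - set(matrix.sample_ids))[:5]
            only_mat = sorted(set(matrix.sample_ids) - set(self.sample_ids))[:5]
            raise FormatError(
                "sample sheet and matrix disagree on sample ids "
                f"(sheet-only: {only_sheet}, matrix-only: {only_mat})"
            )


# ---------------------------------------------------------------------------
# file I/O


def read_expression(path: str | Path, unit: str) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id) into an
    :class:`ExpressionMatrix`. Duplicate ids, missing cells or negative
    abundances raise :class:`FormatError`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), unit)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index_label="sample")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file (set name, description, members; tab-separated)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"GMT line has fewer than 3 fields: {line[:80]!r}")
        name = parts[0]
        if name in sets:
            raise FormatError(f"duplicate gene-set name {name!r}")
        sets[name] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    lines = []
    for name, members in gene_sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *map(str, members)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ortholog_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene_a", "gene_b"]:
        raise FormatError("ortholog table must have columns gene_a, gene_b")
    return df[["gene_a", "gene_b"]]


def write_ortholog_table(table: pd.DataFrame, path: str | Path) -> None:
    table[["gene_a", "gene_b"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# transforms


def to_log2(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(FPKM + pseudocount) transform. Requires unit ``fpkm``."""
    if matrix.unit == "log2fpkm":
        raise UnitError("matrix is already log2-transformed")
    if matrix.unit != "fpkm":
        raise UnitError(f"to_log2 requires fpkm input, got {matrix.unit!r}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    vals = np.log2(matrix.values + pseudocount)
    return ExpressionMatrix(vals, "log2fpkm")


def filter_expressed(matrix: ExpressionMatrix, min_fpkm: float = 1.0,
                     min_samples: int = 1) -> ExpressionMatrix:
    """Keep genes detected at >= ``min_fpkm`` in >= ``min_samples`` samples.

    Idempotent; preserves gene order. The default (FPKM >= 1 in at least one
    sample) is a common operational definition of "expressed".
    """
    if matrix.unit != "fpkm":
        raise UnitError("filter_expressed operates on fpkm matrices")
    keep = (matrix.values >= min_fpkm).sum(axis=1) >= min_samples
    return ExpressionMatrix(matrix.values.loc[keep], matrix.unit)


# ---------------------------------------------------------------------------
# ortholog harmonization


def filter_one_to_one(table: pd.DataFrame) -> pd.DataFrame:
    """Restrict an ortholog table to strictly 1-to-1 rows.

    A row survives only if its gene_a occurs exactly once in the whole table
    and its gene_b occurs exactly once; many-to-one and one-to-many families
    are discarded entirely.
    """
    a_counts = table["gene_a"].value_counts()
    b_counts = table["gene_b"].value_counts()
    keep = table["gene_a"].map(a_counts).eq(1) & table["gene_b"].map(b_counts).eq(1)
    return table.loc[keep].reset_index(drop=True)


def harmonize_orthologs(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    ortholog_table: pd.DataFrame,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict two matrices to 1-to-1 ortholog pairs, rows aligned pairwise.

    Row i of the first output and row i of the second are orthologs per the
    table. Raises :class:`HarmonizationError` with diagnostic counts when no
    pair is present in both matrices.
    """
    strict = filter_one_to_one(ortholog_table)
    in_a = strict["gene_a"].isin(matrix_a.values.index)
    in_b = strict["gene_b"].isin(matrix_b.values.index)
    pairs = strict.loc[in_a & in_b]
    if len(pairs) == 0:
        raise HarmonizationError(
            "no 1-to-1 ortholog pair present in both matrices "
            f"(table rows: {len(ortholog_table)}, strict 1-to-1: {len(strict)}, "
            f"gene_a matched: {int(in_a.sum())}, gene_b matched: {int(in_b.sum())})"
        )
    out_a = ExpressionMatrix(matrix_a.values.loc[pairs["gene_a"].tolist()], matrix_a.unit)
    out_b = ExpressionMatrix(matrix_b.values.loc[pairs["gene_b"].tolist()], matrix_b.unit)
    return out_a, out_b


def map_gene_ids(genes: Iterable[str], ortholog_table: pd.DataFrame,
                 direction: str = "b_to_a") -> dict[str, str]:
    """Dictionary mapping between ortholog namespaces over strict 1-to-1 rows."""
    strict = filter_one_to_one(ortholog_table)
    if direction == "b_to_a":
        lut = dict(zip(strict["gene_b"], strict["gene_a"]))
    elif direction == "a_to_b":
        lut = dict(zip(strict["gene_a"], strict["gene_b"]))
    else:
        raise ValueError("direction must be 'a_to_b' or 'b_to_a'")
    return {g: lut[g] for g in genes if g in lut}
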