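"""Reading, writing and normalising gene x cell expression matrices.

The canonical in-memory orientation is genes as rows, cells as columns,
matching the binary matrix X in {0,1}^(N x L) used downstream. Dense tables
are read with pandas; sparse 10x-style triplets (matrix.mtx + genes.tsv +
barcodes.tsv, CellRanger v2 layout) with scipy.io. Sparse values stay sparse
until a downstream stage needs a single dense gene row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse as sp
from scipy.io import mminfo, mmread, mmwrite

SCALES = ("raw_counts", "normalized", "log")
PLATFORMS = ("smart_seq", "droplet", "unknown")

#: Default fixed KDE bandwidth per platform, on log-scale expression.
#: Full-transcript plate data gets a wider kernel than 3' droplet data.
DEFAULT_BANDWIDTH = {"smart_seq": 0.3, "droplet": 0.05, "unknown": 0.3}


class MatrixParseError(ValueError):
    """A file could not be parsed into a valid expression matrix."""


class MatrixValidationError(ValueError):
    """Parsed data violates an expression-matrix invariant."""


@dataclass
class ExpressionMatrix:
    """Non-negative gene x cell expression matrix.

    Parameters
    ----------
    values : ndarray or scipy sparse matrix, shape (n_genes, n_cells)
        Non-negative expression values; absent sparse entries are zeros.
    gene_ids, cell_ids : sequences of unique strings
        Row and column identifiers.
    scale : {"raw_counts", "normalized", "log"}
        What the numbers mean. Density estimation and binarization require
        ``"log"``; :func:`log_normalize` converts raw counts.
    platform : {"smart_seq", "droplet", "unknown"}
        Assay platform tag; picks the default fixed bandwidth.
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]
    scale: str = "raw_counts"
    platform: str = "unknown"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if sp.issparse(self.values):
            self.values = sp.csr_matrix(self.values)
        else:
            self.values = np.asarray(self.values, dtype=float)
            if self.values.ndim != 2:
                raise MatrixValidationError("values must be a 2-D matrix")
        n, l = self.values.shape
        if n < 1 or l < 1:
            raise MatrixValidationError("matrix must have at least one gene and one cell")
        if len(self.gene_ids) != n:
            raise MatrixValidationError(
                f"{len(self.gene_ids)} gene ids for {n} matrix rows"
            )
        if len(self.cell_ids) != l:
            raise MatrixValidationError(
                f"{len(self.cell_ids)} cell ids for {l} matrix columns"
            )
        for label, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise MatrixValidationError(f"duplicate {label} ids: {dupes[:5]}")
        if self.scale not in SCALES:
            raise MatrixValidationError(f"unknown scale {self.scale!r}")
        if self.platform not in PLATFORMS:
            raise MatrixValidationError(f"unknown platform {self.platform!r}")
        data = self.values.data if sp.issparse(self.values) else self.values
        if data.size and not np.isfinite(data).all():
            raise MatrixValidationError("expression values must be finite")
        # negatives are only meaningful on the log scale (pseudocount < 1)
        if self.scale != "log" and data.size and (data < 0).any():
            raise MatrixValidationError("expression values must be >= 0")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_row(self, i: int) -> np.ndarray:
        """Dense expression vector of gene ``i`` across all cells."""
        if sp.issparse(self.values):
            return np.asarray(self.values[i].todense()).ravel()
        return np.asarray(self.values[i]).ravel()

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return self.values

    def restrict_genes(self, genes: Sequence[str] | Sequence[int]) -> "ExpressionMatrix":
        """Submatrix over the given genes (ids or integer indices), in order."""
        if len(genes) == 0:
            raise MatrixValidationError("empty gene selection")
        if all(isinstance(g, (int, np.integer)) for g in genes):
            idx = [int(g) for g in genes]
        else:
            lookup = {g: i for i, g in enumerate(self.gene_ids)}
            missing = [g for g in genes if g not in lookup]
            if missing:
                raise MatrixValidationError(f"unknown gene ids: {missing[:5]}")
            idx = [lookup[g] for g in genes]
        return replace(
            self,
            values=self.values[idx],
            gene_ids=[self.gene_ids[i] for i in idx],
            cell_ids=list(self.cell_ids),
        )

    @classmethod
    def from_anndata(cls, adata, scale: str = "log", platform: str = "unknown"):
        """Build from an AnnData object (cells x genes; transposed here)."""
        x = adata.X
        values = x.T.copy() if sp.issparse(x) else np.asarray(x).T.copy()
        return cls(
            values=values,
            gene_ids=list(map(str, adata.var_names)),
            cell_ids=list(map(str, adata.obs_names)),
            scale=scale,
            platform=platform,
        )

    def to_anndata(self):
        import anndata

        x = self.values.T.copy() if sp.issparse(self.values) else self.values.T.copy()
        return anndata.AnnData(
            X=x,
            obs=pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )


def read_dense(
    path: str | Path,
    delimiter: str = "\t",
    genes_as_rows: bool = True,
    scale: str = "raw_counts",
    platform: str = "unknown",
) -> ExpressionMatrix:
    """Read a delimited expression table with row and column identifiers.

    First column holds IDs, first row holds the other axis' IDs. With
    ``genes_as_rows=False`` the table is transposed after reading so the
    result is always genes x cells.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise MatrixParseError(f"{path}: no data rows") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise MatrixParseError(f"{path}: no data rows")
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        row = bad.index[0] if len(bad) else "?"
        raise MatrixParseError(
            f"{path}: non-numeric value at row {row!r}, column {col!r}"
        )
    if not genes_as_rows:
        df = df.T
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise MatrixValidationError(f"{path}: duplicate gene ids: {dupes[:5]}")
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=list(map(str, df.index)),
        cell_ids=list(map(str, df.columns)),
        scale=scale,
        platform=platform,
    )


def write_dense(m: ExpressionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    """Write genes-as-rows delimited table readable by :func:`read_dense`."""
    df = pd.DataFrame(m.dense(), index=m.gene_ids, columns=m.cell_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep=delimiter, lineterminator="\n")


def _read_id_column(path: Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_mtx(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    scale: str = "raw_counts",
    platform: str = "droplet",
) -> ExpressionMatrix:
    """Read a matrix-market triplet with gene and barcode ID files.

    Expects the CellRanger v2 layout: coordinate-format, general-symmetry
    ``.mtx`` with genes as rows, plus one ID per line in ``genes.tsv`` and
    ``barcodes.tsv`` (first tab-separated column used).
    """
    matrix_path = Path(matrix_path)
    rows, cols, _entries, fmt, _field, symmetry = mminfo(matrix_path)
    if fmt != "coordinate" or symmetry != "general":
        raise MatrixParseError(
            f"{matrix_path}: coordinate general required, got {fmt} {symmetry}"
        )
    genes = _read_id_column(Path(genes_path))
    barcodes = _read_id_column(Path(barcodes_path))
    if len(genes) != rows:
        raise MatrixValidationError(
            f"{genes_path}: {len(genes)} gene ids but matrix header declares {rows} rows"
        )
    if len(barcodes) != cols:
        raise MatrixValidationError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrix header declares {cols} columns"
        )
    values = sp.csr_matrix(mmread(matrix_path))
    return ExpressionMatrix(
        values=values, gene_ids=genes, cell_ids=barcodes, scale=scale, platform=platform
    )


def write_mtx(m: ExpressionMatrix, directory: str | Path) -> None:
    """Write matrix.mtx / genes.tsv / barcodes.tsv into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    values = m.values if sp.issparse(m.values) else sp.coo_matrix(m.values)
    mmwrite(directory / "matrix.mtx", values)
    (directory / "genes.tsv").write_text(
        "".join(f"{g}\t{g}\n" for g in m.gene_ids)
    )
    (directory / "barcodes.tsv").write_text("".join(f"{c}\n" for c in m.cell_ids))


def log_normalize(
    m: ExpressionMatrix,
    size_factor_target: float = 1e4,
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """Library-size normalise each cell, then log2-transform.

    Each cell's column is scaled to sum to ``size_factor_target`` and every
    entry becomes ``log2(x + pseudocount)``. Cells with zero total counts are
    left all-zero and reported with a warning. Rank order within each cell is
    preserved.
    """
    if m.scale == "log":
        raise MatrixValidationError(
            "matrix is already log-scaled; refusing to transform twice"
        )
    if size_factor_target <= 0 or pseudocount <= 0:
        raise MatrixValidationError("size_factor_target and pseudocount must be > 0")
    if sp.issparse(m.values):
        totals = np.asarray(m.values.sum(axis=0)).ravel()
    else:
        totals = m.values.sum(axis=0)
    zero_cols = totals == 0
    if zero_cols.any():
        warnings.warn(
            f"{int(zero_cols.sum())} cell(s) have zero total counts and are left all-zero",
            stacklevel=2,
        )
    factors = np.where(zero_cols, 1.0, size_factor_target / np.where(zero_cols, 1.0, totals))
    if sp.issparse(m.values):
        scaled = m.values @ sp.diags(factors)
        if pseudocount == 1.0:
            scaled = scaled.tocsr()
            scaled.data = np.log2(scaled.data + 1.0)
            out = scaled
        else:
            # log2(0 + pc) is nonzero for pc != 1, so the result is dense
            out = np.log2(np.asarray(scaled.todense()) + pseudocount)
            out[:, zero_cols] = 0.0
    else:
        scaled = m.values * factors
        out = np.log2(scaled + pseudocount)
        out[:, zero_cols] = 0.0
    return replace(m, values=out, scale="log")
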