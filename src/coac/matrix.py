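"""Expression-matrix container, readers/writers, and gene-level filters.

The canonical in-memory orientation is cells x genes: rows are cells,
columns are genes.  A gene's expression profile across cells is therefore a
*column*, which is the vector that gets projected onto the latent
components downstream.  Sparse input (10x-style MatrixMarket triples) stays
sparse internally; dense delimited tables become dense arrays.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "Transform",
    "ExpressionMatrix",
    "FormatError",
    "load_matrix",
    "save_matrix",
    "load_labels",
    "log_tpm_transform",
    "filter_genes_by_expression_ratio",
]


class FormatError(ValueError):
    """Raised when an on-disk matrix violates its declared format."""


class Transform(str, enum.Enum):
    RAW = "raw"
    LOG_TPM = "log_tpm"


@dataclass
class ExpressionMatrix:
    """Nonnegative expression values with aligned cell and gene identifiers.

    Parameters
    ----------
    values
        ``(n_cells, n_genes)`` nonnegative matrix; dense ndarray or scipy
        sparse (kept sparse).
    gene_ids, cell_ids
        Unique ordered identifiers matching the columns / rows of ``values``.
    transform
        Provenance tag: ``raw`` counts/TPM, or ``log_tpm`` for log(TPM+1).
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]
    transform: Transform = Transform.RAW

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n_cells, n_genes = self.values.shape
        if n_cells != len(self.cell_ids) or n_genes != len(self.gene_ids):
            raise FormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != n_cells:
            raise FormatError("duplicate cell identifiers")
        mn = self.values.min() if not sp.issparse(self.values) else self.values.min()
        if mn < 0:
            raise ValueError("expression values must be nonnegative")
        dense = self.values.toarray() if sp.issparse(self.values) else self.values
        if not np.all(np.isfinite(dense)):
            raise ValueError("expression values must be finite")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        """Dense float ndarray view (copy if sparse)."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def gene_index(self, gene_ids: list[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return np.array([lookup[g] for g in gene_ids], dtype=int)


def load_matrix(
    path: str | Path,
    orientation: str = "cells_by_genes",
    genes_file: str = "genes.tsv",
    barcodes_file: str = "barcodes.tsv",
) -> ExpressionMatrix:
    """Read a 10x-style MTX triple or a dense delimited table.

    ``path`` pointing at a directory (or a ``matrix.mtx`` file) selects the
    MatrixMarket route: ``matrix.mtx`` with ``genes.tsv`` (genes are MTX
    rows) and ``barcodes.tsv``.  Any other file is parsed as a delimited
    table with a header row and an index column; ``orientation`` declares
    whether rows on disk are cells (``cells_by_genes``) or genes
    (``genes_by_cells``).  The result is always cells x genes.
    """
    path = Path(path)
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if path.is_dir() or path.suffix == ".mtx":
        d = path if path.is_dir() else path.parent
        mtx_path = d / "matrix.mtx" if path.is_dir() else path
        try:
            m = scipy.io.mmread(mtx_path)
        except Exception as exc:  # malformed MatrixMarket header/body
            raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc
        genes = _read_id_column(d / genes_file)
        barcodes = _read_id_column(d / barcodes_file)
        if m.shape != (len(genes), len(barcodes)):
            raise FormatError(
                f"matrix is {m.shape} but {len(genes)} genes and "
                f"{len(barcodes)} barcodes were listed"
            )
        # 10x convention: MTX rows are genes; transpose to cells x genes
        values = sp.csr_matrix(m.T)
        if values.nnz and values.data.min() < 0:
            raise ValueError("expression values must be nonnegative")
        return ExpressionMatrix(values, gene_ids=genes, cell_ids=barcodes)

    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "genes_by_cells":
        df = df.T
    return ExpressionMatrix(
        df.to_numpy(dtype=float),
        gene_ids=list(df.columns),
        cell_ids=list(df.index),
    )


def _read_id_column(path: Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def save_matrix(m: ExpressionMatrix, out_dir: str | Path) -> Path:
    """Write an MTX triple (matrix.mtx genes x cells, genes.tsv, barcodes.tsv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = m.values if sp.issparse(m.values) else sp.csr_matrix(m.values)
    scipy.io.mmwrite(out / "matrix.mtx", sp.coo_matrix(mat.T))
    (out / "genes.tsv").write_text("".join(f"{g}\n" for g in m.gene_ids))
    (out / "barcodes.tsv").write_text("".join(f"{c}\n" for c in m.cell_ids))
    return out


def load_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (cell_id, group) into a mapping."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise FormatError("label file needs two columns: cell_id, group")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def log_tpm_transform(m: ExpressionMatrix, rescale_tpm: bool = False) -> ExpressionMatrix:
    """Apply log(x+1), optionally rescaling each cell to TPM (sum 1e6) first.

    Zeros stay zero, so the sparsity pattern is preserved.  Natural log.
    """
    if m.transform is Transform.LOG_TPM:
        raise ValueError("matrix is already log(TPM+1) transformed")
    if sp.issparse(m.values):
        v = m.values.tocsr().astype(float).copy()
        if rescale_tpm:
            totals = np.asarray(v.sum(axis=1)).ravel()
            scale = np.divide(1e6, totals, out=np.zeros_like(totals), where=totals > 0)
            v = sp.diags(scale) @ v
        v.data = np.log1p(v.data)
        out_values: np.ndarray | sp.spmatrix = v
    else:
        v = np.asarray(m.values, dtype=float).copy()
        if rescale_tpm:
            totals = v.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                v = np.where(totals > 0, v / totals * 1e6, 0.0)
        out_values = np.log1p(v)
    return replace(m, values=out_values, transform=Transform.LOG_TPM)


def filter_genes_by_expression_ratio(
    m: ExpressionMatrix, min_ratio: float = 0.03
) -> ExpressionMatrix:
    """Drop genes expressed (value > 0) in fewer than ``min_ratio`` of cells.

    A gene whose expressed-cell fraction equals the threshold is kept; the
    filter removes only fractions strictly below it.
    """
    if not 0.0 <= min_ratio <= 1.0:
        raise ValueError("min_ratio must be in [0, 1]")
    if sp.issparse(m.values):
        nnz = np.asarray((m.values != 0).sum(axis=0)).ravel()
    else:
        nnz = np.count_nonzero(m.values, axis=0)
    ratio = nnz / m.n_cells
    keep = ratio >= min_ratio
    if not keep.any():
        raise ValueError(
            f"expression-ratio filter at {min_ratio} removed all "
            f"{m.n_genes} genes"
        )
    values = m.values[:, keep] if not sp.issparse(m.values) else m.values.tocsc()[:, keep].tocsr()
    return replace(
        m,
        values=values,
        gene_ids=[g for g, k in zip(m.gene_ids, keep) if k],
    )
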