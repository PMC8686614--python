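"""Input/output and assembly of single-cell CRISPR screen data.

A high-MOI screen produces two count matrices over the same cells: a
gene-by-cell UMI matrix (expression) and a gRNA-by-cell UMI matrix
(perturbation detection). Both are exchanged in the CellRanger triplet
dialect — a Matrix Market ``.mtx`` file plus feature and barcode TSVs —
or as dense TSV for small inputs. This module reads and writes those
formats, thresholds gRNA UMI counts into binary presence calls, and
assembles the per-cell technical covariates that every downstream model
conditions on.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger("crtscreen")

DEFAULT_GRNA_THRESHOLD = 5

COVARIATE_COLUMNS = [
    "batch",
    "log_total_umis",
    "log_n_genes_expressed",
    "pct_mito",
    "log_n_grnas",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene-by-cell UMI counts with aligned identifier lists."""

    counts: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValueError("UMI counts must be nonnegative integers")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_counts(self, gene_id: str) -> np.ndarray:
        """Dense count vector for one gene, in cell order."""
        i = self.gene_ids.index(gene_id)
        return np.asarray(self.counts[i].todense()).ravel()


@dataclass
class GrnaMatrix:
    """gRNA-by-cell UMI counts and their thresholded binary assignments."""

    umi_counts: sp.csr_matrix
    assignments: sp.csr_matrix
    threshold_used: int
    grna_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.umi_counts = sp.csr_matrix(self.umi_counts)
        self.assignments = sp.csr_matrix(self.assignments)
        if self.umi_counts.shape != self.assignments.shape:
            raise ValueError("umi_counts and assignments shapes differ")
        if self.assignments.shape != (len(self.grna_ids), len(self.cell_ids)):
            raise ValueError("assignment shape does not match ID lists")

    @property
    def n_grnas(self) -> int:
        return self.assignments.shape[0]

    @property
    def n_cells(self) -> int:
        return self.assignments.shape[1]

    def grna_indicator(self, grna_id: str) -> np.ndarray:
        """Dense 0/1 presence vector for one gRNA, in cell order."""
        g = self.grna_ids.index(grna_id)
        return np.asarray(self.assignments[g].todense()).ravel().astype(np.int8)


@dataclass
class CovariateTable:
    """Per-cell technical covariates, one row per cell in matrix order.

    ``table`` holds the raw covariates (batch as a categorical plus the
    log-scale technical factors); :meth:`design_matrix` one-hot encodes
    batch with a dropped reference level so the GLM design stays full
    rank.
    """

    table: pd.DataFrame  # indexed by cell_id

    def __post_init__(self) -> None:
        missing = [c for c in COVARIATE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"covariate table missing columns: {missing}")
        if self.table[COVARIATE_COLUMNS].isna().any().any():
            raise ValueError("covariate table contains missing values")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.table.index)

    def design_matrix(self, columns: Sequence[str] | None = None) -> np.ndarray:
        """Numeric design matrix Z (no intercept column).

        Batch is one-hot encoded dropping the first (reference) level;
        numeric covariates pass through unchanged.
        """
        cols = list(columns) if columns is not None else COVARIATE_COLUMNS
        parts = []
        for c in cols:
            col = self.table[c]
            if c == "batch" or not pd.api.types.is_numeric_dtype(col):
                dummies = pd.get_dummies(col.astype("category"), drop_first=True)
                parts.append(dummies.to_numpy(dtype=float))
            else:
                parts.append(col.to_numpy(dtype=float)[:, None])
        return np.hstack(parts) if parts else np.empty((len(self.table), 0))


@dataclass
class CellData:
    """Aligned expression, gRNA assignment, and covariate data for one screen."""

    expr: ExpressionMatrix
    grna: GrnaMatrix
    covariates: CovariateTable

    def __post_init__(self) -> None:
        ids = self.expr.cell_ids
        if self.grna.cell_ids != ids or self.covariates.cell_ids != ids:
            raise ValueError("cell IDs/order differ between matrices and covariates")

    @property
    def n_cells(self) -> int:
        return self.expr.n_cells


# ---------------------------------------------------------------------------
# gRNA assignment and covariate computation
# ---------------------------------------------------------------------------

def assign_grnas(umi_counts, threshold: int = DEFAULT_GRNA_THRESHOLD) -> sp.csr_matrix:
    """Threshold gRNA UMI counts into binary presence assignments.

    A gRNA is called present in a cell when its UMI count is greater
    than or equal to ``threshold`` (inclusive rule). gRNAs that end up
    assigned to zero cells are logged as warnings; tests on them will
    fail downstream.
    """
    if threshold < 1:
        raise ValueError("threshold must be a positive integer")
    counts = sp.csr_matrix(umi_counts)
    if counts.data.size and (np.any(counts.data < 0) or np.any(counts.data != np.round(counts.data))):
        raise ValueError("gRNA UMI counts must be nonnegative integers")
    assigned = counts >= threshold
    assigned = sp.csr_matrix(assigned, dtype=np.int8)
    per_grna = np.asarray(assigned.sum(axis=1)).ravel()
    for g, n in enumerate(per_grna):
        logger.info("gRNA row %d: %d cells assigned at threshold %d", g, n, threshold)
        if n == 0:
            logger.warning("gRNA row %d has zero assigned cells at threshold %d", g, threshold)
    return assigned


def build_grna_matrix(
    umi_counts,
    grna_ids: Sequence[str],
    cell_ids: Sequence[str],
    threshold: int = DEFAULT_GRNA_THRESHOLD,
) -> GrnaMatrix:
    counts = sp.csr_matrix(umi_counts)
    return GrnaMatrix(
        umi_counts=counts,
        assignments=assign_grnas(counts, threshold),
        threshold_used=threshold,
        grna_ids=list(grna_ids),
        cell_ids=list(cell_ids),
    )


def compute_cell_covariates(
    expr: ExpressionMatrix,
    grna: GrnaMatrix,
    mito_gene_ids: Iterable[str],
    batch_labels: Sequence,
) -> CovariateTable:
    """Assemble the per-cell technical covariate table.

    Covariates: natural log of total UMIs, natural log of the number of
    expressed genes, percent mitochondrial UMIs (0-100 scale),
    log(1 + number of assigned gRNAs), and the batch label. Cells with
    zero total UMIs cannot be log-transformed and raise; callers should
    drop them first (see :func:`filter_empty_cells`).
    """
    mito = set(mito_gene_ids)
    unknown = mito - set(expr.gene_ids)
    if unknown:
        raise ValueError(f"mito gene IDs not in expression matrix: {sorted(unknown)}")
    if len(batch_labels) != expr.n_cells:
        raise ValueError("batch_labels length does not match number of cells")

    total = np.asarray(expr.counts.sum(axis=0)).ravel()
    if np.any(total == 0):
        bad = int((total == 0).sum())
        raise ValueError(
            f"{bad} cells have zero total UMIs; filter them before computing covariates"
        )
    n_genes_expr = np.asarray((expr.counts > 0).sum(axis=0)).ravel()
    if np.any(n_genes_expr == 0):  # unreachable when total > 0, kept as a guard
        raise ValueError("cells with zero expressed genes present")

    mito_rows = [i for i, g in enumerate(expr.gene_ids) if g in mito]
    if mito_rows:
        mito_umis = np.asarray(expr.counts[mito_rows].sum(axis=0)).ravel()
    else:
        mito_umis = np.zeros(expr.n_cells)
    n_grnas = np.asarray(grna.assignments.sum(axis=0)).ravel()

    table = pd.DataFrame(
        {
            "batch": pd.Categorical(batch_labels),
            "log_total_umis": np.log(total),
            "log_n_genes_expressed": np.log(n_genes_expr),
            "pct_mito": 100.0 * mito_umis / total,
            "log_n_grnas": np.log1p(n_grnas),
        },
        index=pd.Index(expr.cell_ids, name="cell_id"),
    )
    return CovariateTable(table)


def filter_empty_cells(expr: ExpressionMatrix, grna: GrnaMatrix) -> tuple[ExpressionMatrix, GrnaMatrix, np.ndarray]:
    """Drop cells with zero total UMIs or zero expressed genes.

    Returns the filtered matrices and the boolean keep-mask; the number
    of dropped cells is logged, never imputed.
    """
    total = np.asarray(expr.counts.sum(axis=0)).ravel()
    keep = total > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d cells with zero total UMIs", dropped)
    kept_ids = [c for c, k in zip(expr.cell_ids, keep) if k]
    expr_f = ExpressionMatrix(expr.counts[:, keep], expr.gene_ids, kept_ids)
    grna_f = GrnaMatrix(
        grna.umi_counts[:, keep],
        grna.assignments[:, keep],
        grna.threshold_used,
        grna.grna_ids,
        kept_ids,
    )
    return expr_f, grna_f, keep


# ---------------------------------------------------------------------------
# Matrix Market triplet I/O
# ---------------------------------------------------------------------------

def _read_id_file(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip().split("\t")[0] for line in fh if line.strip()]


def read_mtx_triplet(mtx_path: str, features_path: str, barcodes_path: str) -> tuple[sp.csr_matrix, list[str], list[str]]:
    """Read a CellRanger-style triplet (matrix.mtx + features + barcodes)."""
    mat = sp.csr_matrix(mmread(mtx_path))
    features = _read_id_file(features_path)
    barcodes = _read_id_file(barcodes_path)
    if mat.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"matrix shape {mat.shape} inconsistent with {len(features)} features "
            f"and {len(barcodes)} barcodes"
        )
    return mat, features, barcodes


def write_mtx_triplet(matrix, row_ids: Sequence[str], col_ids: Sequence[str], out_dir: str, prefix: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    mat = sp.coo_matrix(matrix)
    mmwrite(os.path.join(out_dir, f"{prefix}.mtx"), mat, field="integer")
    for name, ids in ((f"{prefix}.features.tsv", row_ids), (f"{prefix}.barcodes.tsv", col_ids)):
        with open(os.path.join(out_dir, name), "w") as fh:
            fh.write("\n".join(ids) + "\n")


def read_expression_mtx(mtx_path: str, features_path: str, barcodes_path: str) -> ExpressionMatrix:
    mat, genes, cells = read_mtx_triplet(mtx_path, features_path, barcodes_path)
    return ExpressionMatrix(mat, genes, cells)


def read_grna_mtx(
    mtx_path: str,
    features_path: str,
    barcodes_path: str,
    threshold: int = DEFAULT_GRNA_THRESHOLD,
) -> GrnaMatrix:
    mat, grnas, cells = read_mtx_triplet(mtx_path, features_path, barcodes_path)
    return build_grna_matrix(mat, grnas, cells, threshold)


def read_dense_tsv(path: str) -> tuple[sp.csr_matrix, list[str], list[str]]:
    """Read a small dense matrix TSV (rows = features, header = cell IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return sp.csr_matrix(df.to_numpy()), [str(i) for i in df.index], [str(c) for c in df.columns]


def write_dense_tsv(matrix, row_ids: Sequence[str], col_ids: Sequence[str], path: str) -> None:
    dense = np.asarray(sp.csr_matrix(matrix).todense(), dtype=int)
    pd.DataFrame(dense, index=list(row_ids), columns=list(col_ids)).to_csv(path, sep="\t")


def write_covariates_tsv(cov: CovariateTable, path: str) -> None:
    cov.table.to_csv(path, sep="\t", index_label="cell_id")


def read_covariates_tsv(path: str) -> CovariateTable:
    table = pd.read_csv(path, sep="\t", index_col=0)
    table["batch"] = pd.Categorical(table["batch"])
    return CovariateTable(table)
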