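"""Loading and preprocessing of cells × genes expression matrices.

The pipeline expects a non-negative count matrix with cell and gene
identifiers.  Preprocessing follows the standard single-cell recipe: drop
near-empty cells and rarely detected genes, library-size normalize each cell
to a common total, apply log(1 + x), and keep the top genes by normalized
dispersion (or by total expression).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd


class DegenerateInputError(ValueError):
    """Raised when an operation would produce an empty or invalid result."""


@dataclass
class ExpressionMatrix:
    """A dense cells × genes matrix of non-negative expression values.

    Attributes
    ----------
    values
        ``(n_cells, n_genes)`` float array, non-negative, no missing entries.
    cell_ids, gene_ids
        Unique identifiers for rows and columns.
    is_normalized
        True once :func:`normalize_log` has been applied.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    is_normalized: bool = False
    is_scaled: bool = False  # per-gene standardized values may be negative

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, m = self.values.shape
        if n != len(self.cell_ids) or m != len(self.gene_ids):
            raise ValueError("identifier lengths do not match matrix shape")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell identifiers must be unique")
        if len(set(self.gene_ids)) != m:
            raise ValueError("gene identifiers must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no NaN/Inf)")
        if not self.is_scaled and np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


def _make_unique(names: list[str]) -> list[str]:
    """Deduplicate identifiers by suffixing '-1', '-2', ... (anndata style)."""
    counts: dict[str, int] = {}
    out = []
    for name in names:
        if name in counts:
            counts[name] += 1
            out.append(f"{name}-{counts[name]}")
        else:
            counts[name] = 0
            out.append(name)
    return out


def _find_sidecar(path: Path, stems: tuple[str, ...]) -> Path | None:
    for stem in stems:
        for cand in (path.with_suffix("." + stem), path.parent / f"{stem}.tsv",
                     path.parent / f"{stem}.txt", path.parent / stem):
            if cand.exists() and cand.is_file():
                return cand
    return None


def load_expression(path, fmt: str | None = None, genes_as: str = "columns") -> ExpressionMatrix:
    """Load an expression matrix from CSV/TSV, MatrixMarket MTX, or h5ad.

    Parameters
    ----------
    path
        File to read.  For MTX, companion ``barcodes``/``genes`` text files in
        the same directory supply identifiers when present.
    fmt
        ``"csv"``, ``"mtx"`` or ``"h5ad"``; inferred from the suffix if None.
    genes_as
        Whether genes are stored as ``"columns"`` (cells in rows, the returned
        orientation) or ``"rows"`` (the matrix is transposed on load).
        Ignored for h5ad, which is cells × genes by convention.
    """
    path = Path(path)
    if genes_as not in ("rows", "columns"):
        raise ValueError("genes_as must be 'rows' or 'columns'")
    if fmt is None:
        suffix = path.suffix.lower().lstrip(".")
        fmt = {"csv": "csv", "tsv": "csv", "txt": "csv", "mtx": "mtx", "h5ad": "h5ad"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix of {path.name}")
    if not path.exists():
        raise FileNotFoundError(path)

    if fmt == "csv":
        # read the header line ourselves: pandas mangles duplicate column
        # names, but duplicates must be preserved for our own suffixing rule
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
        sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
        raw_cols = header.split(sep)[1:]
        try:
            df = pd.read_csv(path, sep=sep, index_col=0, skiprows=1, header=None)
            values = df.to_numpy(dtype=np.float64)
        except (ValueError, TypeError) as err:
            raise ValueError(f"non-numeric or malformed entries in {path}: {err}") from err
        if len(raw_cols) != values.shape[1]:
            raise ValueError(f"header of {path} does not match its column count")
        row_ids = [str(i) for i in df.index]
        col_ids = [str(c) for c in raw_cols]
        if genes_as == "rows":
            values = values.T
            cell_ids, gene_ids = col_ids, row_ids
        else:
            cell_ids, gene_ids = row_ids, col_ids
    elif fmt == "mtx":
        from scipy.io import mmread

        values = np.asarray(mmread(path).todense(), dtype=np.float64)
        rows_file = _find_sidecar(path, ("genes", "features")) if genes_as == "rows" else _find_sidecar(path, ("barcodes", "cells"))
        cols_file = _find_sidecar(path, ("barcodes", "cells")) if genes_as == "rows" else _find_sidecar(path, ("genes", "features"))
        row_ids = _read_id_file(rows_file, values.shape[0], "r")
        col_ids = _read_id_file(cols_file, values.shape[1], "c")
        if genes_as == "rows":
            values = values.T
            cell_ids, gene_ids = col_ids, row_ids
        else:
            cell_ids, gene_ids = row_ids, col_ids
    elif fmt == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        x = adata.X
        values = np.asarray(x.todense() if hasattr(x, "todense") else x, dtype=np.float64)
        cell_ids = [str(c) for c in adata.obs_names]
        gene_ids = [str(g) for g in adata.var_names]
    else:
        raise ValueError(f"unknown format {fmt!r}")

    gene_ids = _make_unique(list(gene_ids))
    cell_ids = _make_unique(list(cell_ids))
    return ExpressionMatrix(values=values, cell_ids=cell_ids, gene_ids=gene_ids)


def _read_id_file(path: Path | None, n: int, prefix: str) -> list[str]:
    if path is None:
        return [f"{prefix}{i}" for i in range(n)]
    ids = [line.split("\t")[0].strip() for line in path.read_text().splitlines() if line.strip()]
    if len(ids) != n:
        raise ValueError(f"identifier file {path} has {len(ids)} entries, expected {n}")
    return ids


def filter_cells_genes(
    x: ExpressionMatrix, min_genes_per_cell: int = 200, min_cells_per_gene: int = 3
) -> ExpressionMatrix:
    """Drop cells expressing too few genes, then rarely detected genes.

    The gene filter runs on the already cell-filtered matrix, so removing
    empty cells cannot resurrect a gene.
    """
    if x.is_normalized:
        raise ValueError("filtering must run on raw counts, before normalization")
    if min_genes_per_cell < 1 or min_cells_per_gene < 1:
        raise ValueError("filter thresholds must be positive integers")
    expressed = x.values > 0
    keep_cells = expressed.sum(axis=1) >= min_genes_per_cell
    if not keep_cells.any():
        raise DegenerateInputError("no cells survive the cell filter")
    vals = x.values[keep_cells]
    keep_genes = (vals > 0).sum(axis=0) >= min_cells_per_gene
    if not keep_genes.any():
        raise DegenerateInputError("no genes survive the gene filter")
    return ExpressionMatrix(
        values=vals[:, keep_genes],
        cell_ids=[c for c, k in zip(x.cell_ids, keep_cells) if k],
        gene_ids=[g for g, k in zip(x.gene_ids, keep_genes) if k],
    )


def normalize_log(x: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Scale each cell to ``target_sum`` total counts, then apply log1p."""
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    totals = x.values.sum(axis=1)
    if np.any(totals <= 0):
        raise DegenerateInputError("cells with zero total counts must be filtered first")
    scaled = x.values * (target_sum / totals)[:, None]
    return replace(x, values=np.log1p(scaled), is_normalized=True)


def select_top_genes(
    x: ExpressionMatrix, n_top: int = 2000, criterion: str = "dispersion"
) -> ExpressionMatrix:
    """Keep the ``min(n_top, n_genes)`` top-ranked genes.

    criterion="dispersion" ranks by normalized dispersion as in standard
    highly-variable-gene selection (Seurat-style mean bins, via scanpy);
    criterion="total_expression" ranks by summed expression.  Ties are broken
    by lexicographic gene id, so the retained set does not depend on the
    input gene order.  Retained genes keep their original relative order.
    """
    if n_top <= 0:
        raise ValueError("n_top must be a positive integer")
    if not x.is_normalized:
        raise ValueError("gene selection expects log-normalized data")
    if criterion not in ("dispersion", "total_expression"):
        raise ValueError(f"unknown criterion {criterion!r}")
    k = min(n_top, x.n_genes)

    if criterion == "total_expression":
        score = x.values.sum(axis=0)
    else:
        score = _normalized_dispersion(x)

    order = sorted(range(x.n_genes), key=lambda j: (-score[j], x.gene_ids[j]))
    selected = sorted(order[:k])  # original column order
    return ExpressionMatrix(
        values=x.values[:, selected],
        cell_ids=list(x.cell_ids),
        gene_ids=[x.gene_ids[j] for j in selected],
        is_normalized=True,
    )


def scale_genes(x: ExpressionMatrix, max_value: float | None = None) -> ExpressionMatrix:
    """Standardize each gene to zero mean and unit variance.

    Without this step the rows of a log-normalized matrix are dominated by
    one shared mean-expression direction, which biases any inner-product
    downstream (graph filters, encoder logits) toward a single rank-one
    component.  Constant genes are left at zero.  ``max_value`` optionally
    clips the standardized values at ±max_value.
    """
    if not x.is_normalized:
        raise ValueError("scaling expects log-normalized data")
    mu = x.values.mean(axis=0)
    sd = x.values.std(axis=0)
    vals = (x.values - mu) / np.where(sd > 0, sd, 1.0)
    if max_value is not None:
        vals = np.clip(vals, -max_value, max_value)
    return replace(x, values=vals, is_scaled=True)


def _normalized_dispersion(x: ExpressionMatrix) -> np.ndarray:
    """Seurat-flavor normalized dispersion per gene, computed via scanpy."""
    import anndata as ad
    import scanpy as sc

    adata = ad.AnnData(
        X=x.values.copy(),
        obs=pd.DataFrame(index=pd.Index(x.cell_ids, name="cell")),
        var=pd.DataFrame(index=pd.Index(x.gene_ids, name="gene")),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(adata, flavor="seurat", min_disp=-np.inf, min_mean=-np.inf, max_mean=np.inf)
    disp = adata.var["dispersions_norm"].to_numpy(dtype=np.float64)
    return np.where(np.isfinite(disp), disp, -np.inf)


def save_expression(x: ExpressionMatrix, path, provenance: dict | None = None) -> None:
    """Write the matrix as delimited text plus an optional JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(x.values, index=x.cell_ids, columns=x.gene_ids)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df.to_csv(path, sep=sep)
    if provenance is not None:
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        sidecar.write_text(json.dumps(provenance, indent=2, default=str))
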