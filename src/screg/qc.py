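"""Cell/gene filtering, log-normalization, gene statistics and pseudobulk.

Filtering drops cells with too few detected genes (default < 1000) and
genes seen in too few cells (default < 3).  Normalization is the usual
library-size scaling to 10,000 counts followed by log1p:

    x_gc = ln(1 + count_gc * scale_factor / total_c)

Pseudobulk sums raw counts per group, emulating a bulk library, and RPM
rescales totals to reads per million.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, NormalizedMatrix

__all__ = [
    "filter_cells",
    "filter_genes",
    "log_normalize",
    "gene_stats",
    "pseudobulk",
    "rpm",
]


def filter_cells(m: CountMatrix, min_genes: int = 1000) -> CountMatrix:
    """Keep cells with at least ``min_genes`` detected genes."""
    if min_genes < 0:
        raise ValueError("min_genes must be >= 0")
    keep = m.detected_genes_per_cell() >= min_genes
    return m.subset_cells(keep)


def filter_genes(m: CountMatrix, min_cells: int = 3) -> CountMatrix:
    """Keep genes with nonzero counts in at least ``min_cells`` cells."""
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    keep = m.cells_per_gene() >= min_cells
    return m.subset_genes(keep)


def log_normalize(m: CountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """ln(1 + count * scale_factor / cell_total); zeros map to zeros."""
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = m.counts_per_cell()
    if np.any(totals == 0):
        bad = m.barcodes[np.flatnonzero(totals == 0)[0]]
        raise ValueError(f"cell {bad!r} has zero total counts")
    X = sp.csc_matrix(m.X, dtype=float)
    # scale columns in place on the sparse data to keep zeros implicit
    scale = scale_factor / totals
    X.data *= np.repeat(scale, np.diff(X.indptr))
    X.data = np.log1p(X.data)
    return NormalizedMatrix(sp.csr_matrix(X), m.genes, m.barcodes, scale_factor)


def gene_stats(nm: NormalizedMatrix) -> pd.DataFrame:
    """Per-gene mean and dispersion (variance/mean) of normalized values.

    Sample variance uses n-1; genes that are constant across cells
    (including all-zero genes) get dispersion 0.
    """
    n = nm.n_cells
    if n < 2:
        raise ValueError("gene_stats needs at least 2 cells")
    X = sp.csr_matrix(nm.X)
    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=1)).ravel()
    var = (sq - mean**2) * n / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(var > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    return pd.DataFrame({"mean": mean, "dispersion": disp}, index=nm.genes)


def pseudobulk(m: CountMatrix, labels: pd.Series, groups=None) -> pd.DataFrame:
    """Sum raw counts per group of cells -> genes x groups totals."""
    labels = pd.Series(labels)
    if len(labels) != m.n_cells:
        raise ValueError("labels must cover all cells")
    if groups is None:
        groups = sorted(pd.unique(labels))
    else:
        unknown = set(labels) - set(groups)
        if unknown:
            raise ValueError(f"unknown labels: {sorted(unknown)}")
    out = {}
    lab_arr = labels.to_numpy()
    for g in groups:
        idx = np.flatnonzero(lab_arr == g)
        out[g] = np.asarray(m.X[:, idx].sum(axis=1)).ravel().astype(np.int64)
    return pd.DataFrame(out, index=m.genes)


def rpm(totals: pd.Series) -> pd.Series:
    """Reads per million: count * 1e6 / sum(counts)."""
    totals = pd.Series(totals, dtype=float)
    s = totals.sum()
    if s <= 0:
        raise ValueError("cannot compute RPM of an all-zero profile")
    return totals * 1e6 / s
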