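"""Core in-memory containers shared across the pipeline.

The central object is a sparse gene-by-cell count matrix with string
gene identifiers and cell barcodes.  Cells are columns, genes are rows,
matching the orientation of a 10x-style MatrixMarket triplet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["CountMatrix", "NormalizedMatrix", "Regulon"]


def _check_axes(X, genes: pd.Index, barcodes: pd.Index) -> None:
    if X.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"matrix shape {X.shape} inconsistent with {len(genes)} genes "
            f"x {len(barcodes)} barcodes"
        )
    if genes.has_duplicates:
        raise ValueError("duplicate gene IDs")
    if barcodes.has_duplicates:
        raise ValueError("duplicate cell barcodes")


@dataclass
class CountMatrix:
    """Raw integer counts, genes x cells, stored sparse (CSR)."""

    X: sp.csr_matrix
    genes: pd.Index
    barcodes: pd.Index

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.genes = pd.Index(self.genes)
        self.barcodes = pd.Index(self.barcodes)
        _check_axes(self.X, self.genes, self.barcodes)
        if self.X.nnz and self.X.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]

    def counts_per_cell(self) -> np.ndarray:
        """Total counts (library size) of every cell."""
        return np.asarray(self.X.sum(axis=0)).ravel()

    def detected_genes_per_cell(self) -> np.ndarray:
        """Number of genes with count > 0 in every cell."""
        return np.asarray((self.X > 0).sum(axis=0)).ravel()

    def cells_per_gene(self) -> np.ndarray:
        """Number of cells in which every gene has count > 0."""
        return np.asarray((self.X > 0).sum(axis=1)).ravel()

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        return CountMatrix(self.X[:, idx], self.genes, self.barcodes[idx])

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        return CountMatrix(self.X[idx, :], self.genes[idx], self.barcodes)


@dataclass
class NormalizedMatrix:
    """Log-normalized expression, genes x cells; zeros stay zero."""

    X: sp.csr_matrix
    genes: pd.Index
    barcodes: pd.Index
    scale_factor: float = 10_000.0

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.genes = pd.Index(self.genes)
        self.barcodes = pd.Index(self.barcodes)
        _check_axes(self.X, self.genes, self.barcodes)
        if self.X.nnz and not np.all(np.isfinite(self.X.data)):
            raise ValueError("non-finite normalized values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]

    def dense(self) -> np.ndarray:
        return self.X.toarray()


@dataclass
class Regulon:
    """A transcription factor with its weighted, signed target list.

    ``mor`` is the mode of regulation in [-1, 1] (sign: activation vs
    repression); ``likelihood`` in (0, 1] is the confidence weight of
    each TF-target edge.
    """

    tf: str
    targets: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    mor: np.ndarray = field(default_factory=lambda: np.empty(0))
    likelihood: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=object)
        self.mor = np.asarray(self.mor, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        n = len(self.targets)
        if len(self.mor) != n or len(self.likelihood) != n:
            raise ValueError("targets, mor and likelihood must be aligned")
        if n < 2:
            raise ValueError("a regulon needs at least 2 targets")
        if len(set(self.targets)) != n:
            raise ValueError("duplicate targets in regulon")
        if self.tf in self.targets:
            raise ValueError("TF cannot be its own target")
        if np.any(np.abs(self.mor) > 1):
            raise ValueError("mode of regulation must lie in [-1, 1]")
        if np.any((self.likelihood <= 0) | (self.likelihood > 1)):
            raise ValueError("likelihood must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.targets)
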