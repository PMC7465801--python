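"""Count-matrix container and on-disk format.

A :class:`CountDataset` bundles a sparse gene-by-cell matrix of raw counts
with per-cell metadata (including the ground-truth subpopulation label
``phenoid`` and quality flags) and per-gene annotations (mitochondrial /
ribosomal / protein-coding flags). Datasets round-trip losslessly through a
directory of plain-text files: Matrix Market ``matrix.mtx`` plus
``features.tsv``, ``barcodes.tsv`` and ``cell_meta.csv``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["CountDataset", "read_dataset", "write_dataset"]


@dataclass
class CountDataset:
    """Raw counts (genes x cells) with cell and gene annotations.

    ``cell_meta`` is indexed by barcode and carries at least ``phenoid``
    (truth label), ``is_doublet`` and ``is_lowq`` flags; ``gene_meta`` is
    indexed by gene id and carries boolean ``is_mito``, ``is_ribo`` and
    ``is_coding`` columns.
    """

    counts: sp.csr_matrix
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_meta), len(self.cell_meta)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_meta)} genes x {len(self.cell_meta)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def barcodes(self) -> pd.Index:
        return self.cell_meta.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.gene_meta.index

    def subset_cells(self, mask: np.ndarray) -> "CountDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountDataset(
            self.counts[:, idx], self.cell_meta.iloc[idx].copy(), self.gene_meta.copy()
        )

    def subset_genes(self, mask: np.ndarray) -> "CountDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountDataset(
            self.counts[idx], self.cell_meta.copy(), self.gene_meta.iloc[idx].copy()
        )

    def equals(self, other: "CountDataset") -> bool:
        return (
            self.counts.shape == other.counts.shape
            and (self.counts != other.counts).nnz == 0
            and self.cell_meta.equals(other.cell_meta)
            and self.gene_meta.equals(other.gene_meta)
        )


def write_dataset(ds: CountDataset, path: str) -> None:
    """Write a dataset as matrix.mtx + features.tsv + barcodes.tsv + cell_meta.csv."""
    os.makedirs(path, exist_ok=True)
    scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), sp.coo_matrix(ds.counts))
    ds.gene_meta.to_csv(os.path.join(path, "features.tsv"), sep="\t")
    with open(os.path.join(path, "barcodes.tsv"), "w") as fh:
        fh.write("\n".join(map(str, ds.barcodes)) + "\n")
    ds.cell_meta.to_csv(os.path.join(path, "cell_meta.csv"))


def read_dataset(path: str) -> CountDataset:
    """Read a dataset directory written by :func:`write_dataset`.

    Raises ``ValueError`` when the metadata row counts do not match the
    matrix dimensions.
    """
    counts = sp.csr_matrix(scipy.io.mmread(os.path.join(path, "matrix.mtx")))
    gene_meta = pd.read_csv(os.path.join(path, "features.tsv"), sep="\t", index_col=0)
    with open(os.path.join(path, "barcodes.tsv")) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    cell_meta = pd.read_csv(os.path.join(path, "cell_meta.csv"), index_col=0)
    cell_meta.index = cell_meta.index.astype(str)
    if len(barcodes) != counts.shape[1]:
        raise ValueError(
            f"barcodes.tsv has {len(barcodes)} rows but matrix has "
            f"{counts.shape[1]} columns"
        )
    if len(gene_meta) != counts.shape[0]:
        raise ValueError(
            f"features.tsv has {len(gene_meta)} rows but matrix has "
            f"{counts.shape[0]} rows"
        )
    if list(map(str, cell_meta.index)) != barcodes:
        raise ValueError("cell_meta.csv index does not match barcodes.tsv")
    # integer counts stored as reals by mmwrite round-trip safely
    counts.data = np.asarray(counts.data)
    if np.allclose(counts.data, np.round(counts.data)):
        counts = counts.astype(np.int64)
    return CountDataset(counts, cell_meta, gene_meta)
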