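"""Core data container for paired spliced/unspliced count matrices.

The central object of the pipeline is :class:`VelocityDataset`: two
aligned count layers (spliced and unspliced molecule counts) over the
same genes and cells, plus a per-cell metadata table. Matrices are kept
cells x genes (the anndata/scanpy convention); genes and cells are
always addressed by string identifier, never by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


def _as_csr(x) -> sp.csr_matrix:
    if sp.issparse(x):
        return x.tocsr()
    return sp.csr_matrix(np.asarray(x))


@dataclass
class VelocityDataset:
    """Paired spliced/unspliced counts with aligned per-cell metadata.

    Parameters
    ----------
    spliced, unspliced
        Non-negative count matrices, cells x genes, identical shape.
    var_names
        Gene identifiers (length = number of genes, unique).
    obs
        Per-cell metadata; the index holds the cell identifiers.
        Conventional columns: ``cluster``, ``total_counts``,
        ``n_genes``, ``mito_fraction``.
    embedding
        Optional 2-D (or higher) per-cell embedding, cells x dims.
    """

    spliced: sp.csr_matrix
    unspliced: sp.csr_matrix
    var_names: pd.Index
    obs: pd.DataFrame
    embedding: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.spliced = _as_csr(self.spliced)
        self.unspliced = _as_csr(self.unspliced)
        self.var_names = pd.Index(self.var_names)
        if self.spliced.shape != self.unspliced.shape:
            raise ValueError(
                f"layer shapes differ: spliced {self.spliced.shape} vs "
                f"unspliced {self.unspliced.shape}"
            )
        n_cells, n_genes = self.spliced.shape
        if len(self.var_names) != n_genes:
            raise ValueError(f"{len(self.var_names)} gene names for {n_genes} columns")
        if not self.var_names.is_unique:
            raise ValueError("gene identifiers must be unique")
        if len(self.obs) != n_cells:
            raise ValueError(f"metadata has {len(self.obs)} rows for {n_cells} cells")
        if not self.obs.index.is_unique:
            raise ValueError("cell identifiers must be unique")
        for name, layer in (("spliced", self.spliced), ("unspliced", self.unspliced)):
            if layer.nnz and layer.data.min() < 0:
                raise ValueError(f"negative counts in {name} layer")
        if self.embedding is not None:
            self.embedding = np.asarray(self.embedding, dtype=float)
            if self.embedding.shape[0] != n_cells:
                raise ValueError("embedding rows do not match the number of cells")

    # -- basic introspection -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.spliced.shape[0]

    @property
    def n_genes(self) -> int:
        return self.spliced.shape[1]

    @property
    def obs_names(self) -> pd.Index:
        return self.obs.index

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"VelocityDataset({self.n_cells} cells x {self.n_genes} genes, "
            f"obs: {list(self.obs.columns)})"
        )

    # -- subsetting ----------------------------------------------------------
    def subset_cells(self, keep) -> "VelocityDataset":
        """Return a dataset restricted to ``keep`` (boolean mask or cell ids)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = self.obs.index.get_indexer(keep)
            if (idx < 0).any():
                missing = np.asarray(keep)[idx < 0][:5]
                raise KeyError(f"unknown cell identifiers: {list(missing)}")
        return VelocityDataset(
            spliced=self.spliced[idx],
            unspliced=self.unspliced[idx],
            var_names=self.var_names,
            obs=self.obs.iloc[idx].copy(),
            embedding=None if self.embedding is None else self.embedding[idx],
        )

    def subset_genes(self, genes) -> "VelocityDataset":
        idx = self.var_names.get_indexer(genes)
        if (idx < 0).any():
            missing = [g for g, i in zip(genes, idx) if i < 0][:5]
            raise KeyError(f"unknown gene identifiers: {missing}")
        return VelocityDataset(
            spliced=self.spliced[:, idx],
            unspliced=self.unspliced[:, idx],
            var_names=self.var_names[idx],
            obs=self.obs.copy(),
            embedding=self.embedding,
        )

    def copy(self) -> "VelocityDataset":
        return VelocityDataset(
            spliced=self.spliced.copy(),
            unspliced=self.unspliced.copy(),
            var_names=self.var_names.copy(),
            obs=self.obs.copy(),
            embedding=None if self.embedding is None else self.embedding.copy(),
        )

    # -- interchange ---------------------------------------------------------
    def to_anndata(self):
        """Export as an :class:`anndata.AnnData` with spliced/unspliced layers."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.spliced.copy(),
            obs=self.obs.copy(),
            var=pd.DataFrame(index=self.var_names.copy()),
        )
        adata.layers["spliced"] = self.spliced.copy()
        adata.layers["unspliced"] = self.unspliced.copy()
        if self.embedding is not None:
            adata.obsm["X_embed"] = self.embedding.copy()
        return adata
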