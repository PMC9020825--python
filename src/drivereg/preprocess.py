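"""Cell filtering, normalization, covariate regression and neighbors.

Mirrors the standard droplet workflow every downstream stage assumes:
discard high-mitochondrial cells (strictly more than the threshold
fraction, 0.20 by default), scale each cell to the median depth and
log1p, regress nuisance covariates (cell-cycle score, mitochondrial
fraction, detected genes, total UMI) out of each gene by ordinary least
squares, then build a Euclidean kNN graph on a PCA embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .datasets import VelocityDataset


@dataclass
class QCThresholds:
    """Cell-level quality thresholds (fractions/counts, inclusive keeps)."""

    max_mito_fraction: float = 0.20
    min_genes: int | None = None
    min_counts: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")


@dataclass
class ProcessedMatrix:
    """PCA embedding plus kNN graph over the retained cells."""

    embedding: np.ndarray            # cells x n_pcs
    knn_indices: np.ndarray          # cells x k (self excluded)
    knn_distances: np.ndarray
    obs_names: pd.Index
    explained_variance_ratio: np.ndarray

    @property
    def k(self) -> int:
        return self.knn_indices.shape[1]


def mito_fraction(dataset: VelocityDataset, mito_prefix: str = "mt-") -> pd.Series:
    """Per-cell mitochondrial fraction of spliced counts."""
    mito = dataset.var_names.str.lower().str.startswith(mito_prefix.lower())
    tot = np.asarray(dataset.spliced.sum(axis=1)).ravel()
    sub = np.asarray(dataset.spliced[:, np.flatnonzero(mito)].sum(axis=1)).ravel()
    frac = np.divide(sub, tot, out=np.zeros_like(sub, dtype=float), where=tot > 0)
    return pd.Series(frac, index=dataset.obs_names, name="mito_fraction")


def filter_cells(dataset: VelocityDataset, thresholds: QCThresholds | None = None,
                 mito_prefix: str = "mt-") -> VelocityDataset:
    """Drop cells failing QC; both layers and metadata subset consistently.

    A cell is discarded when its mitochondrial fraction is *strictly*
    greater than ``max_mito_fraction`` (a cell at exactly the threshold
    is retained), or when it falls below the optional ``min_genes`` /
    ``min_counts`` floors. Uses the ``mito_fraction`` metadata column
    when present, otherwise computes it from genes named ``mt-*``.
    """
    thresholds = thresholds or QCThresholds()
    if "mito_fraction" in dataset.obs:
        frac = dataset.obs["mito_fraction"].to_numpy(float)
    else:
        frac = mito_fraction(dataset, mito_prefix).to_numpy()
    keep = frac <= thresholds.max_mito_fraction
    if thresholds.min_genes is not None:
        keep &= np.asarray((dataset.spliced > 0).sum(axis=1)).ravel() >= thresholds.min_genes
    if thresholds.min_counts is not None:
        keep &= np.asarray(dataset.spliced.sum(axis=1)).ravel() >= thresholds.min_counts
    if not keep.any():
        raise ValueError("all cells removed by QC filtering")
    return dataset.subset_cells(keep)


def normalize_log(dataset: VelocityDataset, layer: str = "spliced") -> pd.DataFrame:
    """Median-depth scaling followed by log(1 + x).

    Returns a dense cells x genes DataFrame. Deterministic; raises on a
    zero-depth cell (it cannot be scaled).
    """
    counts = getattr(dataset, layer)
    depth = np.asarray(counts.sum(axis=1)).ravel().astype(float)
    if (depth == 0).any():
        bad = dataset.obs_names[depth == 0][:5]
        raise ValueError(f"zero-depth cells cannot be normalized: {list(bad)}")
    target = np.median(depth)
    X = np.asarray(counts.todense(), dtype=float) * (target / depth)[:, None]
    return pd.DataFrame(np.log1p(X), index=dataset.obs_names, columns=dataset.var_names)


def normalize_depth(dataset: VelocityDataset, layer: str = "spliced") -> pd.DataFrame:
    """Median-depth scaling without the log — the scale velocity fits use."""
    counts = getattr(dataset, layer)
    depth = np.asarray(counts.sum(axis=1)).ravel().astype(float)
    safe = np.where(depth > 0, depth, 1.0)
    target = np.median(depth[depth > 0]) if (depth > 0).any() else 1.0
    X = np.asarray(counts.todense(), dtype=float) * (target / safe)[:, None]
    return pd.DataFrame(X, index=dataset.obs_names, columns=dataset.var_names)


def regress_covariates(expr: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """OLS-residualize each gene on the covariates, preserving gene means.

    Fits, per gene, expression ~ intercept + covariates and returns
    residuals with the gene mean restored, so downstream scores keep
    their scale. Raises on rank-deficient designs, naming the collinear
    columns.
    """
    if not expr.index.equals(covariates.index):
        covariates = covariates.reindex(expr.index)
        if covariates.isna().any().any():
            raise ValueError("covariate table does not cover all cells")
    C = covariates.to_numpy(float)
    design = np.column_stack([np.ones(len(C)), C])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by incremental rank growth
        collinear = []
        cols = [np.ones(len(C))]
        for name, col in zip(covariates.columns, C.T):
            trial = np.column_stack(cols + [col])
            if np.linalg.matrix_rank(trial) == len(cols):
                collinear.append(str(name))
            else:
                cols.append(col)
        raise ValueError(f"rank-deficient covariate matrix; collinear columns: {collinear}")
    Y = expr.to_numpy(float)
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ coef
    resid += Y.mean(axis=0, keepdims=True)
    return pd.DataFrame(resid, index=expr.index, columns=expr.columns)


def pca_neighbors(expr: pd.DataFrame, n_pcs: int = 30, k: int = 30,
                  seed: int | None = 0) -> ProcessedMatrix:
    """PCA embedding and Euclidean kNN graph (self excluded).

    ``n_pcs`` is capped at min(cells, genes) - 1; ``k`` must be smaller
    than the number of cells.
    """
    n_cells, n_genes = expr.shape
    if k >= n_cells:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n_cells})")
    n_pcs = min(n_pcs, n_cells - 1, n_genes)
    X = expr.to_numpy(float)
    pca = PCA(n_components=n_pcs, svd_solver="full" if min(expr.shape) < 1000 else "randomized",
              random_state=seed)
    emb = pca.fit_transform(X - X.mean(axis=0, keepdims=True))
    nn = NearestNeighbors(n_neighbors=k + 1, metric="euclidean").fit(emb)
    dist, idx = nn.kneighbors(emb)
    # drop the self column; guard against ties placing self later
    out_idx = np.empty((n_cells, k), dtype=int)
    out_dist = np.empty((n_cells, k))
    for i in range(n_cells):
        row = idx[i]
        drow = dist[i]
        mask = row != i
        if mask.sum() == k + 1:      # self not returned (exact duplicate ties)
            mask[-1] = False
        out_idx[i] = row[mask][:k]
        out_dist[i] = drow[mask][:k]
    return ProcessedMatrix(
        embedding=emb,
        knn_indices=out_idx,
        knn_distances=out_dist,
        obs_names=expr.index,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
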