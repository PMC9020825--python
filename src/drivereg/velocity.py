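"""Steady-state RNA velocity and phase-portrait driver-gene ranking.

Velocity is estimated per gene from the imbalance between unspliced (u)
and spliced (s) abundance: cells at transcriptional equilibrium fall on
the steady-state line u = gamma_hat * s, induced genes sit above it and
repressed genes below, so v = u - gamma_hat * s has the sign of the
transcriptional change. gamma_hat is fit on the extreme-quantile cells
of the phase portrait (where equilibrium holds best), on kNN-smoothed,
depth-normalized abundances.

Driver genes — the genes whose portrait dynamics best explain a
cluster's trajectory — are ranked by ``driver_score = fit_r2 x
normalized dynamic range``, where fit_r2 is the coefficient of
determination of a two-segment (induction/repression) piecewise-linear
fit with segments assigned by the sign of u - gamma_hat * s, and the
dynamic range is the spread of spliced abundance across the cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datasets import VelocityDataset
from .preprocess import normalize_depth


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def moments(dataset: VelocityDataset, knn_indices: np.ndarray):
    """First-order kNN-averaged, depth-normalized (u, s) matrices.

    Each cell's profile is replaced by the mean over itself and its k
    nearest neighbors, the usual denoising step before kinetics fits.
    Returns ``(Mu, Ms)`` DataFrames, cells x genes.
    """
    out = []
    for layer in ("unspliced", "spliced"):
        X = normalize_depth(dataset, layer=layer).to_numpy()
        n, k = knn_indices.shape
        sm = (X + X[knn_indices].sum(axis=1)) / (k + 1)
        out.append(pd.DataFrame(sm, index=dataset.obs_names, columns=dataset.var_names))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# per-gene kinetics fit
# ---------------------------------------------------------------------------

def _two_segment_r2(u: np.ndarray, s: np.ndarray, gamma_hat: float) -> float:
    """R^2 of a two-line fit with segments split by sign of u - gamma*s."""
    sst = float(((u - u.mean()) ** 2).sum())
    if sst == 0.0:
        return 0.0
    sse = 0.0  # degenerate segments fall back to their mean
    d = u - gamma_hat * s
    for m in (d >= 0, d < 0):
        if m.sum() >= 2 and np.ptp(s[m]) > 0:
            b, a = np.polyfit(s[m], u[m], 1)
            sse += float(((u[m] - (a + b * s[m])) ** 2).sum())
        elif m.any():
            sse += float(((u[m] - u[m].mean()) ** 2).sum())
    return float(np.clip(1.0 - sse / sst, 0.0, 1.0))


def fit_gamma(u, s, extreme_quantile: float = 0.05, min_cells: int = 10,
              quantiles: tuple = (0.05, 0.95)) -> pd.DataFrame:
    """Per-gene steady-state ratio fit on phase-portrait extremes.

    For each gene, cells in the lower and upper ``extreme_quantile`` of
    spliced abundance are taken to be near equilibrium, and gamma_hat is
    the slope of the zero-intercept least-squares fit of u on s over
    those cells. Also reports the two-segment fit R^2, the spliced
    dynamic range (spread between the ``quantiles``), and the number of
    expressing cells. Genes with fewer than ``min_cells`` expressing
    cells, or a non-positive slope, are flagged unfit.

    Parameters
    ----------
    u, s
        Smoothed unspliced/spliced abundances, cells x genes
        (DataFrames or arrays of identical shape).
    """
    if not 0 < extreme_quantile <= 0.5:
        raise ValueError("extreme_quantile must lie in (0, 0.5]")
    u_df = pd.DataFrame(u)
    s_df = pd.DataFrame(s)
    U, S = u_df.to_numpy(float), s_df.to_numpy(float)
    genes = s_df.columns

    rows = []
    for j in range(S.shape[1]):
        sj, uj = S[:, j], U[:, j]
        expressed = int((sj > 0).sum())
        rec = {"gene": genes[j], "n_expressed": expressed, "gamma_hat": np.nan,
               "fit_r2": np.nan, "dynamic_range": np.nan,
               "dynamic_range_lo": np.nan, "dynamic_range_hi": np.nan,
               "fitted": False}
        if expressed >= min_cells:
            lo = np.quantile(sj, extreme_quantile)
            hi = np.quantile(sj, 1.0 - extreme_quantile)
            m = (sj <= lo) | (sj >= hi)
            denom = float((sj[m] ** 2).sum())
            if denom > 0:
                g = float((uj[m] * sj[m]).sum() / denom)
                if g > 0:
                    q_lo = float(np.quantile(sj, quantiles[0]))
                    q_hi = float(np.quantile(sj, quantiles[1]))
                    rec.update(
                        gamma_hat=g,
                        fit_r2=_two_segment_r2(uj, sj, g),
                        dynamic_range=q_hi - q_lo,
                        dynamic_range_lo=q_lo,
                        dynamic_range_hi=q_hi,
                        fitted=True,
                    )
        rows.append(rec)
    return pd.DataFrame(rows).set_index("gene")


def compute_velocity(u, s, fits: pd.DataFrame) -> pd.DataFrame:
    """Velocity v = u - gamma_hat * s on the fitted genes (cells x genes)."""
    u_df, s_df = pd.DataFrame(u), pd.DataFrame(s)
    keep = fits.index[fits["fitted"].astype(bool)]
    gam = fits.loc[keep, "gamma_hat"].to_numpy()
    V = u_df[keep].to_numpy(float) - s_df[keep].to_numpy(float) * gam[None, :]
    return pd.DataFrame(V, index=s_df.index, columns=keep)


@dataclass
class VelocityField:
    """Velocity matrix with its neighbor-graph projections."""

    velocity: pd.DataFrame                       # cells x fitted genes
    graph: sp.csr_matrix | None = field(default=None)   # cosine(v_i, x_j - x_i) on kNN
    confidence: pd.Series | None = field(default=None)  # per-cell coherence in [-1, 1]


def velocity_graph(velocity: pd.DataFrame, expression, knn_indices: np.ndarray) -> sp.csr_matrix:
    """Cosine score between each cell's velocity and its neighbor displacements.

    For cell i and neighbor j the score is cos(v_i, x_j - x_i) in the
    space of fitted genes; a cell with zero velocity scores 0 against
    all neighbors. Returned as a sparse cells x cells matrix on the kNN
    sparsity pattern.
    """
    X = pd.DataFrame(expression)[velocity.columns].to_numpy(float)
    V = velocity.to_numpy(float)
    n, k = knn_indices.shape
    rows = np.repeat(np.arange(n), k)
    cols = knn_indices.ravel()
    data = np.zeros(n * k)
    vnorm = np.linalg.norm(V, axis=1)
    for i in range(n):
        if vnorm[i] == 0:
            continue
        nbr = knn_indices[i]
        diff = X[nbr] - X[i]
        dn = np.linalg.norm(diff, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosv = np.where(dn > 0, diff @ V[i] / (dn * vnorm[i]), 0.0)
        data[i * k:(i + 1) * k] = cosv
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def velocity_confidence(velocity: pd.DataFrame, knn_indices: np.ndarray) -> pd.Series:
    """Mean cosine similarity between a cell's velocity and its neighbors'.

    High where the local flow is coherent (committed domains), low at
    fate branchpoints where neighbors point apart. Cells with zero
    velocity are reported as NaN (undefined direction).
    """
    V = velocity.to_numpy(float)
    norm = np.linalg.norm(V, axis=1)
    ok = norm > 0
    N = np.zeros_like(V)
    N[ok] = V[ok] / norm[ok, None]
    cos = np.einsum("ij,ikj->ik", N, N[knn_indices])  # cos(v_i, v_j), 0 where undefined
    conf = cos.mean(axis=1)
    conf[~ok] = np.nan
    return pd.Series(conf, index=velocity.index, name="velocity_confidence")


# ---------------------------------------------------------------------------
# driver genes
# ---------------------------------------------------------------------------

def rank_driver_genes(u, s, labels: pd.Series, cluster: str, top_n: int = 100,
                      extreme_quantile: float = 0.05, min_cells: int = 10,
                      min_cluster_cells: int = 20,
                      exclude_prefixes: tuple = ("mt-",)) -> pd.DataFrame:
    """Rank a cluster's driver genes by phase-portrait dynamics.

    Fits kinetics within the cluster's cells only and scores each gene
    by ``fit_r2 x (dynamic_range / max dynamic_range)``, so top genes
    both follow a clean induction/repression portrait and traverse a
    wide expression range — the transcriptomically active genes of the
    cluster. Mitochondrial genes are excluded by default, as in standard
    velocity workflows. Returns the top ``top_n`` fitted genes (fewer if
    fewer genes are eligible) with their fit statistics.
    """
    u_df, s_df = pd.DataFrame(u), pd.DataFrame(s)
    labels = pd.Series(labels)
    if cluster not in set(labels):
        raise KeyError(f"cluster {cluster!r} not present in labels")
    cells = labels.index[labels == cluster]
    if len(cells) < min_cluster_cells:
        raise ValueError(f"cluster {cluster!r} has {len(cells)} cells; "
                         f"need at least {min_cluster_cells}")
    keep_genes = [g for g in s_df.columns
                  if not any(str(g).lower().startswith(p.lower()) for p in exclude_prefixes)]
    fits = fit_gamma(u_df.loc[cells, keep_genes], s_df.loc[cells, keep_genes],
                     extreme_quantile=extreme_quantile, min_cells=min_cells)
    fits = fits[fits["fitted"]].copy()
    # relative contrast in [0, 1]: 1 when the gene sweeps from silence to its
    # maximum, ~0 for a flat gene; scale-invariant so highly expressed but
    # static genes do not outrank genuine switches
    lo = fits["dynamic_range_lo"]
    hi = fits["dynamic_range_hi"]
    with np.errstate(invalid="ignore", divide="ignore"):
        contrast = ((hi - lo) / (hi + lo)).where(hi + lo > 0, other=0.0)
    fits["norm_dynamic_range"] = contrast.clip(0.0, 1.0)
    fits["driver_score"] = fits["fit_r2"] * fits["norm_dynamic_range"]
    fits = fits.sort_index().sort_values("driver_score", ascending=False, kind="stable")
    return fits.head(min(top_n, len(fits)))
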