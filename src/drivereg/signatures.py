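"""Compartment annotation, marker detection and coexpression scoring.

Cells are labelled myogenic or non-myogenic by a simple marker rule
(expressing the myogenic ligand marker, Pdgfa-like, or any canonical
myogenic gene → myogenic; otherwise non-myogenic). Per-cell myogenic
and non-myogenic signature scores are sums of normalized log expression
over the top compartment markers; dividing each by their sum gives two
fractions s_m + s_n = 1, whose product c = s_m * s_n is the
coexpression score (maximal 0.25 when both programs are equally
active). Cells with c strictly above 0.20 are called "transition"
cells — the bipotent interface between the two fates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import VelocityDataset


@dataclass
class MarkerConfig:
    """Marker genes driving the compartment annotation rule."""

    ligand_marker: str                # Pdgfa-like, expressed by myogenic cells
    myogenic_genes: tuple             # Myf5/Myod/Myog-like
    receptor_marker: str | None = None  # Pdgfra-like, informational


def annotate_compartments(dataset: VelocityDataset, markers: MarkerConfig) -> pd.Series:
    """Label each cell myogenic or non-myogenic from raw marker counts.

    A cell is myogenic iff it has any count of the ligand marker OR of
    any myogenic gene; all remaining cells are non-myogenic.
    """
    needed = [markers.ligand_marker, *markers.myogenic_genes]
    missing = [g for g in needed if g not in dataset.var_names]
    if missing:
        raise KeyError(f"marker genes absent from the gene universe: {missing}")
    idx = dataset.var_names.get_indexer(needed)
    counts = np.asarray(dataset.spliced[:, idx].todense())
    myo = (counts > 0).any(axis=1)
    return pd.Series(np.where(myo, "myogenic", "non-myogenic"),
                     index=dataset.obs_names, name="compartment")


def find_markers(expr: pd.DataFrame, labels: pd.Series, group: str,
                 n_top: int = 10) -> pd.DataFrame:
    """Rank the genes over-expressed in ``group`` versus all other cells.

    Two-sided Wilcoxon rank-sum (tie-corrected normal approximation) per
    gene plus the log fold change (difference of group means on the log
    scale). Only genes with positive fold change are kept, ranked by
    p-value then by fold change. ``n_top`` defaults to 10, the signature
    size; use 20 for heatmap-style marker panels.
    """
    labels = pd.Series(labels).reindex(expr.index)
    in_group = (labels == group).to_numpy()
    if in_group.sum() < 3 or (~in_group).sum() < 3:
        raise ValueError(f"need >= 3 cells in and out of group {group!r}")
    X = expr.to_numpy(float)
    A, B = X[in_group], X[~in_group]
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(A, B, alternative="two-sided", axis=0, method="asymptotic")
    lfc = A.mean(axis=0) - B.mean(axis=0)
    table = pd.DataFrame({
        "p_value": res.pvalue,
        "log_fold_change": lfc,
        "mean_in": A.mean(axis=0),
        "mean_out": B.mean(axis=0),
    }, index=expr.columns)
    table = table[table["log_fold_change"] > 0]
    table = table.sort_values(["p_value", "log_fold_change"], ascending=[True, False],
                              kind="stable")
    return table.head(n_top)


@dataclass
class SignatureResult:
    """Per-cell signature fractions, coexpression score and ordering."""

    scores: pd.DataFrame     # S_m, S_n, s_m, s_n, coexpression (+ transition, order)
    genes_myogenic: tuple
    genes_nonmyogenic: tuple
    threshold: float | None = None

    @property
    def transition_cells(self) -> pd.Index:
        if "transition" not in self.scores:
            raise AttributeError("transition not yet called; run coexpression_transition")
        return self.scores.index[self.scores["transition"].fillna(False).astype(bool)]


def signature_scores(expr: pd.DataFrame, genes_myo, genes_nonmyo) -> SignatureResult:
    """Aggregate normalized log expression into two compartment fractions.

    ``S_m``/``S_n`` are the summed expression over each signature set;
    each is divided by their sum to give fractions ``s_m + s_n = 1``.
    Cells silent for both sets are flagged missing (NaN fractions)
    rather than set to 0.5/0.5, which would fabricate maximal
    coexpression from silence.
    """
    genes_myo, genes_nonmyo = list(genes_myo), list(genes_nonmyo)
    if not genes_myo or not genes_nonmyo:
        raise ValueError("signature gene sets must be non-empty")
    overlap = set(genes_myo) & set(genes_nonmyo)
    if overlap:
        raise ValueError(f"signature sets overlap: {sorted(overlap)}")
    missing = [g for g in genes_myo + genes_nonmyo if g not in expr.columns]
    if missing:
        raise KeyError(f"signature genes absent from expression matrix: {missing}")
    S_m = expr[genes_myo].sum(axis=1)
    S_n = expr[genes_nonmyo].sum(axis=1)
    tot = S_m + S_n
    with np.errstate(invalid="ignore", divide="ignore"):
        s_m = np.where(tot > 0, S_m / tot, np.nan)
    scores = pd.DataFrame({
        "S_m": S_m, "S_n": S_n,
        "s_m": s_m, "s_n": 1.0 - s_m,
        "coexpression": s_m * (1.0 - s_m),
    }, index=expr.index)
    return SignatureResult(scores=scores, genes_myogenic=tuple(genes_myo),
                           genes_nonmyogenic=tuple(genes_nonmyo))


def coexpression_transition(result: SignatureResult, threshold: float = 0.20) -> SignatureResult:
    """Flag transition cells and order cells by rising non-myogenic fraction.

    A cell is a transition cell iff its coexpression score is *strictly*
    greater than ``threshold`` (default 0.20; the score is bounded by
    0.25, reached at s_m = s_n = 0.5). Cells with undefined scores are
    never flagged. The ordering ranks cells by s_n ascending with a
    stable tie-break on the cell identifier — the display order of the
    transition heatmap.
    """
    import warnings

    if not 0.0 <= threshold <= 0.25:
        warnings.warn(f"threshold {threshold} is outside the attainable range [0, 0.25]",
                      stacklevel=2)
    scores = result.scores.copy()
    c = scores["coexpression"]
    scores["transition"] = (c > threshold).where(c.notna(), other=False)
    order = scores.assign(_cell=scores.index).sort_values(
        ["s_n", "_cell"], kind="stable")
    scores["order_rank"] = pd.Series(np.arange(len(order)), index=order.index)
    return SignatureResult(scores=scores, genes_myogenic=result.genes_myogenic,
                           genes_nonmyogenic=result.genes_nonmyogenic,
                           threshold=threshold)
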