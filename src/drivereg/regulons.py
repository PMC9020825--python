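"""Regulon gene sets and recovery-curve (AUC) activity scoring.

A regulon is a transcription factor together with its target genes,
consumed here as a GMT gene-set file (discovery itself — motif pruning
against cisTarget databases — is upstream and out of scope). Activity
is scored per cell AUCell-style: genes are ranked by descending
expression, the recovery curve counts how many targets appear within
the top ``top_fraction`` of ranks, and the area under that curve is
normalized by the maximum achievable area (all targets at the very
top), giving a value in [0, 1] that is invariant to any monotone
transform of the cell's expression vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RegulonSet:
    """Map TF name -> target gene list, with optional ``_extended`` flags."""

    regulons: dict
    extended: set = field(default_factory=set)

    def __post_init__(self) -> None:
        for tf, targets in self.regulons.items():
            if not targets:
                raise ValueError(f"regulon {tf} has an empty target list")
            self.regulons[tf] = list(dict.fromkeys(targets))  # dedupe, keep order

    def __len__(self) -> int:
        return len(self.regulons)

    def __iter__(self):
        return iter(self.regulons.items())

    def __getitem__(self, tf):
        return self.regulons[tf]

    def intersect_universe(self, genes) -> tuple["RegulonSet", dict]:
        """Restrict targets to the gene universe; report what was dropped."""
        genes = set(genes)
        kept, dropped = {}, {}
        for tf, targets in self.regulons.items():
            inside = [g for g in targets if g in genes]
            gone = [g for g in targets if g not in genes]
            if gone:
                dropped[tf] = gone
            if inside:
                kept[tf] = inside
        return RegulonSet(kept, extended=self.extended & set(kept)), dropped

    def subset(self, tfs) -> "RegulonSet":
        return RegulonSet({tf: list(self.regulons[tf]) for tf in tfs},
                          extended=self.extended & set(tfs))


def read_regulons(path) -> RegulonSet:
    """Parse a GMT file (name, description, targets...) into a RegulonSet.

    Duplicate TF entries are merged with the union of their targets;
    lines with an empty target list are skipped with a warning. A TF
    name ending in ``_extended`` marks a lower-confidence regulon (flag
    preserved, suffix kept in the name).
    """
    regs: dict[str, list] = {}
    extended = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, "
                                 f"description and targets")
            name, _desc, *targets = parts
            targets = [t for t in targets if t]
            if not targets:
                warnings.warn(f"{path}:{lineno}: regulon {name} has no targets; skipped",
                              stacklevel=2)
                continue
            regs.setdefault(name, [])
            regs[name] = list(dict.fromkeys(regs[name] + targets))
            if name.endswith("_extended"):
                extended.add(name)
    return RegulonSet(regs, extended=extended)


def write_regulons(regulon_set: RegulonSet, path) -> None:
    with open(path, "w") as fh:
        for tf, targets in regulon_set:
            fh.write("\t".join([tf, "."] + list(targets)) + "\n")


# ---------------------------------------------------------------------------
# AUC activity
# ---------------------------------------------------------------------------

def _expression_ranks(values: np.ndarray) -> np.ndarray:
    """Order of gene indices by descending value, ties broken by gene order."""
    n = values.shape[-1]
    return np.lexsort((np.arange(n), -values))


def regulon_auc(expr: pd.DataFrame, targets, top_fraction: float = 0.05) -> pd.Series:
    """Per-cell recovery-curve AUC of a single regulon's targets.

    For each cell the genes are ranked by descending expression
    (deterministic tie-break on gene order); the recovery curve is the
    cumulative count of targets at ranks 1..cutoff with cutoff =
    ceil(top_fraction * n_genes); the AUC is the area under the curve
    divided by the maximum achievable area. 1.0 means all targets lead
    the ranking, 0.0 means none are inside the cutoff.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must lie in (0, 1]")
    targets = [g for g in targets if g in expr.columns]
    if not targets:
        raise ValueError("no regulon target is present in the gene universe")
    n_genes = expr.shape[1]
    cutoff = int(np.ceil(top_fraction * n_genes))
    is_target = expr.columns.isin(targets).astype(float)
    X = expr.to_numpy(float)

    m = min(len(targets), cutoff)
    max_area = float(np.minimum(np.arange(1, cutoff + 1), m).sum())
    aucs = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        order = _expression_ranks(X[i])
        hits = np.cumsum(is_target[order[:cutoff]])
        aucs[i] = hits.sum() / max_area
    return pd.Series(aucs, index=expr.index, name="auc")


def regulon_auc_matrix(expr: pd.DataFrame, regulon_set: RegulonSet,
                       top_fraction: float = 0.05) -> pd.DataFrame:
    """Regulons x cells AUC activity matrix."""
    restricted, _ = regulon_set.intersect_universe(expr.columns)
    rows = {tf: regulon_auc(expr, targets, top_fraction) for tf, targets in restricted}
    return pd.DataFrame(rows).T


def differential_regulon_activity(activity: pd.DataFrame, labels: pd.Series,
                                  cluster: str, top_k: int = 30) -> pd.DataFrame:
    """Rank regulons by mean activity in a cluster versus the rest.

    The ranking statistic is the difference of mean AUC (cluster minus
    rest); a Mann–Whitney U statistic and p-value are reported alongside
    but not used for ranking. Returns the ``top_k`` most
    cluster-elevated regulons.
    """
    labels = pd.Series(labels).reindex(activity.columns)
    in_cluster = (labels == cluster).to_numpy()
    if in_cluster.sum() < 3:
        raise ValueError(f"cluster {cluster!r} has fewer than 3 cells")
    A = activity.to_numpy(float)
    mean_in = A[:, in_cluster].mean(axis=1)
    mean_rest = A[:, ~in_cluster].mean(axis=1)
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(A[:, in_cluster], A[:, ~in_cluster],
                                 alternative="two-sided", axis=1, method="asymptotic")
    table = pd.DataFrame({
        "mean_in_cluster": mean_in,
        "mean_rest": mean_rest,
        "difference": mean_in - mean_rest,
        "u_statistic": res.statistic,
        "p_value": res.pvalue,
    }, index=activity.index)
    table = table.sort_index().sort_values("difference", ascending=False, kind="stable")
    return table.head(min(top_k, len(table)))


def coexpression_regulons(expr: pd.DataFrame, tf_genes, min_corr: float = 0.3,
                          min_targets: int = 5) -> RegulonSet:
    """Correlation-threshold regulon builder for synthetic tests only.

    Assigns to each TF the genes whose expression correlates with it
    above ``min_corr`` (Pearson, excluding the TF itself). This is a
    deliberately simple stand-in for motif-based discovery, used to
    create test regulons from generated data.
    """
    X = expr.to_numpy(float)
    Xc = X - X.mean(axis=0, keepdims=True)
    sd = Xc.std(axis=0)
    regs = {}
    for tf in tf_genes:
        j = expr.columns.get_loc(tf)
        if sd[j] == 0:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (Xc * Xc[:, [j]]).mean(axis=0) / (sd * sd[j])
        targets = [g for g, c in zip(expr.columns, corr)
                   if g != tf and np.isfinite(c) and c >= min_corr]
        if len(targets) >= min_targets:
            regs[tf] = targets
    return RegulonSet(regs)
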