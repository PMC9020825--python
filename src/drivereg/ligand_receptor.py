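"""Ligand–receptor complementarity between the two compartments.

For each gene, the compartment log-ratio is log2 of the myogenic mean
over the non-myogenic mean (with a pseudocount); the pair score is the
ligand's ratio minus the receptor's. A positive score means the ligand
is produced on the myogenic side and received on the non-myogenic side
(Pdgf-like, myogenic -> non-myogenic signalling); a negative score the
reverse (Bmp/Eph-like). The score is exactly antisymmetric under
swapping the two compartment labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class LRPair:
    ligand: str
    receptor: str
    pathway: str = ""

    def __post_init__(self) -> None:
        if self.ligand == self.receptor:
            raise ValueError("ligand and receptor must differ")


def read_lr_pairs(path) -> list:
    """Read a (ligand, receptor, pathway) TSV into LRPair objects."""
    table = pd.read_csv(path, sep="\t")
    needed = {"ligand", "receptor"}
    if not needed <= set(table.columns):
        raise ValueError(f"pair table must have columns {sorted(needed)}")
    return [LRPair(r.ligand, r.receptor, getattr(r, "pathway", ""))
            for r in table.itertuples(index=False)]


def write_lr_pairs(pairs, path) -> None:
    pd.DataFrame([{"ligand": p.ligand, "receptor": p.receptor, "pathway": p.pathway}
                  for p in pairs]).to_csv(path, sep="\t", index=False)


def compartment_ratio(expr: pd.DataFrame, annotation: pd.Series, gene: str,
                      pseudocount: float = 0.01,
                      compartments: tuple = ("myogenic", "non-myogenic")) -> float:
    """log2 ratio of a gene's mean expression, first vs second compartment."""
    if gene not in expr.columns:
        raise KeyError(f"gene {gene!r} absent from expression matrix")
    annotation = pd.Series(annotation).reindex(expr.index)
    a, b = compartments
    in_a = (annotation == a).to_numpy()
    in_b = (annotation == b).to_numpy()
    if not in_a.any() or not in_b.any():
        raise ValueError(f"empty compartment among {compartments}")
    x = expr[gene].to_numpy(float)
    return float(np.log2((x[in_a].mean() + pseudocount) / (x[in_b].mean() + pseudocount)))


def lr_score(pairs, expr: pd.DataFrame, annotation: pd.Series,
             pseudocount: float = 0.01,
             compartments: tuple = ("myogenic", "non-myogenic")) -> pd.DataFrame:
    """Score every ligand–receptor pair; pairs with missing genes are skipped.

    Returns a table with the two compartment log-ratios and
    ``score = ratio(ligand) - ratio(receptor)``.
    """
    import warnings

    rows = []
    for p in pairs:
        missing = [g for g in (p.ligand, p.receptor) if g not in expr.columns]
        if missing:
            warnings.warn(f"pair {p.ligand}-{p.receptor}: missing genes {missing}; skipped",
                          stacklevel=2)
            continue
        rl = compartment_ratio(expr, annotation, p.ligand, pseudocount, compartments)
        rr = compartment_ratio(expr, annotation, p.receptor, pseudocount, compartments)
        rows.append({"ligand": p.ligand, "receptor": p.receptor, "pathway": p.pathway,
                     "ligand_ratio": rl, "receptor_ratio": rr, "score": rl - rr})
    return pd.DataFrame(rows, columns=["ligand", "receptor", "pathway",
                                       "ligand_ratio", "receptor_ratio", "score"])
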