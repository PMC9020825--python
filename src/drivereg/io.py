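"""Readers and writers for the on-disk pipeline formats.

Count layers travel as 10x-style directories — Matrix Market triplet
(genes x cells, optionally gzipped) plus ``features.tsv`` and
``barcodes.tsv`` — one directory per layer. Cell metadata, marker
tables and all results are TSV; regulons are GMT; ligand–receptor pairs
are TSV; simulation truth is JSON. Genes and cells are reconciled by
identifier, never by file position.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datasets import VelocityDataset
from .regulons import RegulonSet, write_regulons
from .simulate import SimulationTruth


def _open_maybe_gz(base: Path):
    """Open ``base`` or ``base.gz``, whichever exists."""
    if base.exists():
        return open(base, "rb")
    gz = base.with_name(base.name + ".gz")
    if gz.exists():
        return gzip.open(gz, "rb")
    raise FileNotFoundError(f"neither {base} nor {gz} exists")


def write_10x_dir(matrix: sp.spmatrix, var_names, obs_names, outdir,
                  compress: bool = False) -> None:
    """Write one count layer as matrix.mtx + features.tsv + barcodes.tsv.

    ``matrix`` is cells x genes in memory and stored genes x cells on
    disk (the 10x convention).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mtx = sp.coo_matrix(matrix.T)
    if compress:
        with gzip.open(outdir / "matrix.mtx.gz", "wb") as fh:
            scipy.io.mmwrite(fh, mtx)
    else:
        scipy.io.mmwrite(outdir / "matrix.mtx", mtx)
    pd.Series(list(var_names)).to_csv(outdir / "features.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(list(obs_names)).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      index=False, header=False)


def read_10x_dir(indir):
    """Read one layer directory; returns (csr cells x genes, genes, barcodes)."""
    indir = Path(indir)
    with _open_maybe_gz(indir / "matrix.mtx") as fh:
        try:
            mtx = scipy.io.mmread(fh)
        except ValueError as err:
            raise ValueError(f"malformed Matrix Market file in {indir}: {err}") from err
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    mat = sp.csr_matrix(mtx.T)
    if mat.shape != (len(cells), len(genes)):
        raise ValueError(
            f"{indir}: matrix is {mtx.shape} (genes x cells) but features/barcodes "
            f"list {len(genes)} genes and {len(cells)} cells")
    return mat, pd.Index(genes, name="gene"), pd.Index(cells, name="cell")


def read_velocity_dataset(spliced_dir, unspliced_dir, metadata_path=None) -> VelocityDataset:
    """Assemble a VelocityDataset from paired layer directories.

    Barcodes and features must agree as *sets* across layers; order
    mismatches are reconciled by identifier. Metadata (TSV, first
    column = cell id) is aligned the same way.
    """
    s_mat, s_genes, s_cells = read_10x_dir(spliced_dir)
    u_mat, u_genes, u_cells = read_10x_dir(unspliced_dir)
    for kind, a, b in (("barcode", s_cells, u_cells), ("feature", s_genes, u_genes)):
        diff = set(a).symmetric_difference(set(b))
        if diff:
            raise ValueError(f"{kind} sets differ between layers; first differences: "
                             f"{sorted(diff)[:5]}")
    if not u_cells.equals(s_cells) or not u_genes.equals(s_genes):
        u_df = pd.DataFrame.sparse.from_spmatrix(u_mat, index=u_cells, columns=u_genes)
        u_mat = sp.csr_matrix(u_df.loc[s_cells, s_genes].sparse.to_coo())
    obs = pd.DataFrame(index=s_cells)
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0, comment="#")
        meta.index = meta.index.astype(str)
        missing = set(s_cells) - set(meta.index)
        if missing:
            raise ValueError(f"metadata misses cells: {sorted(missing)[:5]}")
        obs = meta.loc[s_cells]
    return VelocityDataset(spliced=s_mat, unspliced=u_mat, var_names=s_genes, obs=obs)


def write_velocity_dataset(dataset: VelocityDataset, outdir, compress: bool = False) -> None:
    """Write both layers plus metadata under ``outdir``."""
    outdir = Path(outdir)
    write_10x_dir(dataset.spliced, dataset.var_names, dataset.obs_names,
                  outdir / "spliced", compress)
    write_10x_dir(dataset.unspliced, dataset.var_names, dataset.obs_names,
                  outdir / "unspliced", compress)
    dataset.obs.to_csv(outdir / "metadata.tsv", sep="\t")


def write_benchmark(dataset: VelocityDataset, truth: SimulationTruth, outdir,
                    compress: bool = False) -> None:
    """Write the full synthetic benchmark: layers, metadata, truth, regulons, pairs."""
    outdir = Path(outdir)
    write_velocity_dataset(dataset, outdir, compress)
    write_regulons(RegulonSet(dict(truth.regulon_map)), outdir / "regulons.gmt")
    pd.DataFrame(
        [{"ligand": l, "receptor": r, "pathway": p, "expected_sign": sgn}
         for l, r, p, sgn in truth.ligand_receptor_pairs]
    ).to_csv(outdir / "lr_pairs.tsv", sep="\t", index=False)
    payload = {
        "driver_genes": list(truth.driver_genes),
        "regulon_map": {k: list(v) for k, v in truth.regulon_map.items()},
        "signature_genes_myo": list(truth.signature_genes_myo),
        "signature_genes_nonmyo": list(truth.signature_genes_nonmyo),
        "ligand_receptor_pairs": [list(p) for p in truth.ligand_receptor_pairs],
        "t_switch": truth.t_switch,
        "branch_b_tf": truth.branch_b_tf,
        "marker_config": truth.marker_config,
        "mito_fraction": truth.mito_fraction.round(6).to_dict(),
        "branch": truth.branch.to_dict(),
        "t": truth.t.round(6).to_dict(),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth(path) -> SimulationTruth:
    """Reload a truth JSON written by :func:`write_benchmark` (no latents)."""
    with open(path) as fh:
        payload = json.load(fh)
    return SimulationTruth(
        driver_genes=payload["driver_genes"],
        regulon_map=payload["regulon_map"],
        signature_genes_myo=payload["signature_genes_myo"],
        signature_genes_nonmyo=payload["signature_genes_nonmyo"],
        ligand_receptor_pairs=[tuple(p) for p in payload["ligand_receptor_pairs"]],
        mito_fraction=pd.Series(payload["mito_fraction"]),
        branch=pd.Series(payload["branch"]),
        t=pd.Series(payload["t"]),
        t_switch=payload["t_switch"],
        branch_b_tf=payload["branch_b_tf"],
        marker_config=payload["marker_config"],
    )


def write_table(df: pd.DataFrame, path, config_hash: str = "", seed=None, index=True) -> None:
    """Write a result TSV stamped with the run's config hash and seed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)
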