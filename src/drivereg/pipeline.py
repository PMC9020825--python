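"""End-to-end orchestration of the analysis stages.

The canonical order: QC filter -> normalize -> regress covariates ->
PCA/kNN -> kNN-smoothed moments -> velocity driver ranking (in the
non-myogenic cluster) -> compartment annotation, signatures and
transition calling -> regulon AUC activity and differential ranking ->
driver-regulator network -> ligand–receptor scores. Each stage is a
plain function over the library types so the steps can also be run (and
tested) in isolation; :func:`analyze_dataset` chains them for one
dataset, and :func:`recurrence_across_runs` combines several analyses
into the cross-dataset recurrence table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ligand_receptor as lr
from .config import PipelineConfig
from .datasets import VelocityDataset
from .driver_regulators import (build_driver_network, cross_dataset_recurrence,
                                identify_driver_regulators)
from .preprocess import filter_cells, normalize_log, pca_neighbors, regress_covariates
from .regulons import RegulonSet, differential_regulon_activity, regulon_auc_matrix
from .signatures import (MarkerConfig, annotate_compartments, coexpression_transition,
                         find_markers, signature_scores)
from .velocity import moments, rank_driver_genes, velocity_confidence, compute_velocity, fit_gamma

DEFAULT_COVARIATES = ("cc_score", "mito_fraction", "n_genes", "total_counts")
NONMYO_CLUSTER = "branchB"


@dataclass
class AnalysisResult:
    """Everything one dataset's run produces."""

    dataset: VelocityDataset
    expression: pd.DataFrame                   # normalized (and regressed) log expression
    Mu: pd.DataFrame
    Ms: pd.DataFrame
    drivers: pd.DataFrame                      # ranked driver table (non-myogenic cluster)
    compartments: pd.Series
    markers_myo: pd.DataFrame
    markers_nonmyo: pd.DataFrame
    signatures: object
    regulon_activity: pd.DataFrame | None
    active_regulons: pd.DataFrame | None
    network: object | None
    driver_regulators: set = field(default_factory=set)
    lr_scores: pd.DataFrame | None = None
    velocity_confidence: pd.Series | None = None


def start_of_trajectory_cells(signatures, labels: pd.Series, cluster: str,
                              tercile: float = 1 / 3) -> pd.Index:
    """Cells at the start of a cluster's trajectory: lowest s_n fraction.

    Operationalizes "start of the non-myogenic trajectory" as the
    cluster cells in the lowest ``tercile`` of the non-myogenic
    signature fraction (closest to the myogenic state).
    """
    labels = pd.Series(labels)
    cells = labels.index[labels == cluster]
    sn = signatures.scores.loc[cells, "s_n"].dropna().sort_values(kind="stable")
    n = max(int(np.ceil(len(sn) * tercile)), 1)
    return sn.index[:n]


def analyze_dataset(dataset: VelocityDataset, regulon_set: RegulonSet | None,
                    markers: MarkerConfig, config: PipelineConfig | None = None,
                    lr_pairs=None, cluster: str = NONMYO_CLUSTER,
                    covariates=DEFAULT_COVARIATES, restrict_driver_start: bool = False,
                    compute_confidence: bool = False) -> AnalysisResult:
    """Run the full stage chain on one dataset.

    ``restrict_driver_start`` re-ranks the driver list on the start-of-
    trajectory cells (used for the driver-regulator network);
    otherwise drivers are ranked on the whole cluster.
    """
    cfg = config or PipelineConfig()

    ds = filter_cells(dataset, cfg.qc)
    expr = normalize_log(ds)
    cov = [c for c in covariates if c in ds.obs.columns]
    if cov:
        expr = regress_covariates(expr, ds.obs[cov])
    pm = pca_neighbors(expr, n_pcs=cfg.velocity.n_pcs, k=cfg.velocity.smoothing_k,
                       seed=cfg.seed)
    Mu, Ms = moments(ds, pm.knn_indices)
    labels = ds.obs["cluster"]

    # --- compartments and signatures ---------------------------------------
    compartments = annotate_compartments(ds, markers)
    markers_myo = find_markers(expr, compartments, "myogenic",
                               n_top=cfg.signatures.n_top_markers)
    markers_nonmyo = find_markers(expr, compartments, "non-myogenic",
                                  n_top=cfg.signatures.n_top_markers)
    sig = signature_scores(expr, markers_myo.index, markers_nonmyo.index)
    sig = coexpression_transition(sig, cfg.signatures.coexpression_threshold)

    # --- velocity drivers ----------------------------------------------------
    if restrict_driver_start:
        start = start_of_trajectory_cells(sig, labels, cluster,
                                          cfg.driver_regulators.start_tercile)
        drivers = rank_driver_genes(Mu.loc[start], Ms.loc[start],
                                    labels.loc[start], cluster,
                                    top_n=cfg.velocity.top_n_drivers,
                                    extreme_quantile=cfg.velocity.extreme_quantile)
    else:
        drivers = rank_driver_genes(Mu, Ms, labels, cluster,
                                    top_n=cfg.velocity.top_n_drivers,
                                    extreme_quantile=cfg.velocity.extreme_quantile)

    conf = None
    if compute_confidence:
        fits = fit_gamma(Mu, Ms, extreme_quantile=cfg.velocity.extreme_quantile)
        vel = compute_velocity(Mu, Ms, fits)
        conf = velocity_confidence(vel, pm.knn_indices)

    # --- regulons and the driver-regulator network ---------------------------
    activity = active = network = None
    tf_set: set = set()
    if regulon_set is not None and len(regulon_set):
        activity = regulon_auc_matrix(expr, regulon_set, cfg.regulons.top_fraction)
        active = differential_regulon_activity(activity, labels, cluster,
                                               top_k=cfg.regulons.top_k_active)
        network = build_driver_network(drivers.index, regulon_set.subset(active.index))
        tf_set = identify_driver_regulators(
            network, cfg.driver_regulators.min_driver_targets)

    scores = None
    if lr_pairs:
        scores = lr.lr_score(lr_pairs, expr, compartments)

    return AnalysisResult(
        dataset=ds, expression=expr, Mu=Mu, Ms=Ms, drivers=drivers,
        compartments=compartments, markers_myo=markers_myo,
        markers_nonmyo=markers_nonmyo, signatures=sig,
        regulon_activity=activity, active_regulons=active, network=network,
        driver_regulators=tf_set, lr_scores=scores, velocity_confidence=conf,
    )


def analyze_benchmark(sim_config=None, config: PipelineConfig | None = None,
                      seed: int = 0, **kwargs):
    """Generate a benchmark simulation and run the full analysis on it.

    Returns ``(AnalysisResult, SimulationTruth)``. The regulons and
    marker/ligand configuration consumed by the analysis come from the
    simulation truth, exactly as a user would consume externally
    supplied regulon and pair files.
    """
    from .simulate import build_benchmark_dataset

    ds, truth = build_benchmark_dataset(sim_config, seed=seed)
    regs = RegulonSet({k: list(v) for k, v in truth.regulon_map.items()})
    markers = MarkerConfig(
        ligand_marker=truth.marker_config["ligand_marker"],
        myogenic_genes=tuple(truth.marker_config["myogenic_genes"]),
        receptor_marker=truth.marker_config.get("receptor_marker"),
    )
    pairs = [lr.LRPair(ligand, receptor, pathway)
             for ligand, receptor, pathway, _sign in truth.ligand_receptor_pairs]
    res = analyze_dataset(ds, regs, markers, config=config, lr_pairs=pairs, **kwargs)
    return res, truth


def recurrence_across_runs(results) -> "pd.DataFrame":
    """Recurrence table from several analyses' driver-regulator sets."""
    if isinstance(results, dict):
        sets = {k: r.driver_regulators for k, r in results.items()}
    else:
        sets = [r.driver_regulators for r in results]
    return cross_dataset_recurrence(sets)


def driver_precision(drivers: pd.DataFrame, truth_drivers, top_n: int = 100) -> float:
    """Fraction of the top-``top_n`` ranked genes that are planted drivers."""
    top = list(drivers.index[:top_n])
    if not top:
        return 0.0
    truth_set = set(truth_drivers)
    return sum(g in truth_set for g in top) / len(top)
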