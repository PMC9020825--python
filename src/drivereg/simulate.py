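"""Synthetic bifurcating-lineage generator with known kinetics.

Emulates the structure of a lineage-traced embryonic head dataset: a
shared progenitor population that splits into a myogenic-like branch
(branch A) and a connective-tissue-like branch (branch B). Transcription
follows the standard two-species splicing kinetics

    du/dt = alpha - beta * u        (unspliced)
    ds/dt = beta * u - gamma * s    (spliced)

with a per-gene transcription rate ``alpha`` that may switch to a
branch-specific value at ``t_switch``. The closed-form solution per
constant-alpha segment is used throughout; branch segments start from
the progenitor state at the switch so trajectories are continuous.

Planted structure (all recorded in :class:`SimulationTruth`):

* driver genes — genes whose effective branch-B transcription rate
  differs from the progenitor rate (up- and down-switching);
* regulons — TF genes with co-expressed target modules (target output
  scaled by the TF's own latent expression); one TF switches on in
  branch B and its targets are drivers;
* myogenic / non-myogenic signature genes (anticorrelated between the
  branches) and two ligand–receptor pairs with opposite compartment
  bias (a Pdgf-like pair signalling myogenic -> non-myogenic and a
  Bmp-like pair the other way);
* mitochondrial genes plus a small high-mito "bad cell" subpopulation,
  so the QC filter has work to do;
* overdispersed (gamma–Poisson) count noise with an unspliced capture
  depth well below the spliced depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datasets import VelocityDataset

PROGENITOR = "progenitor"
BRANCH_A = "branchA"  # myogenic-like
BRANCH_B = "branchB"  # non-myogenic (connective-tissue)-like
BRANCHES = (PROGENITOR, BRANCH_A, BRANCH_B)


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

@dataclass
class KineticParams:
    """Per-gene splicing kinetics with a branch-specific rate switch.

    ``alpha_*`` are transcription rates (molecules per unit time),
    ``beta`` the splicing rate and ``gamma`` the degradation rate (both
    per unit time). At ``t_switch`` the transcription rate changes from
    ``alpha_progenitor`` to the branch-specific value.
    """

    alpha_progenitor: np.ndarray
    alpha_branch_a: np.ndarray
    alpha_branch_b: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    t_switch: float

    def __post_init__(self) -> None:
        arrs = {}
        for name in ("alpha_progenitor", "alpha_branch_a", "alpha_branch_b", "beta", "gamma"):
            arrs[name] = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            setattr(self, name, arrs[name])
        n = {a.shape for a in arrs.values()}
        if len(n) != 1:
            raise ValueError("kinetic parameter arrays must share one shape")
        if (self.beta <= 0).any() or (self.gamma <= 0).any():
            raise ValueError("beta and gamma must be strictly positive")
        for name in ("alpha_progenitor", "alpha_branch_a", "alpha_branch_b"):
            if (arrs[name] < 0).any():
                raise ValueError(f"{name} must be non-negative")
        if self.t_switch < 0:
            raise ValueError("t_switch must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.beta.shape[0]


def kinetics_closed_form(u0, s0, alpha, beta, gamma, tau):
    """Closed-form (u, s) after time ``tau`` under constant rates.

    Solves du/dt = alpha - beta*u, ds/dt = beta*u - gamma*s from the
    initial state (u0, s0). All arguments broadcast; the degenerate
    beta == gamma case is handled by its analytic limit.
    """
    u0, s0 = np.asarray(u0, float), np.asarray(s0, float)
    alpha = np.asarray(alpha, float)
    beta, gamma = np.asarray(beta, float), np.asarray(gamma, float)
    tau = np.asarray(tau, float)
    if (beta <= 0).any() or (gamma <= 0).any():
        raise ValueError("beta and gamma must be strictly positive")

    eb = np.exp(-beta * tau)
    eg = np.exp(-gamma * tau)
    du0 = u0 - alpha / beta
    u = alpha / beta + du0 * eb

    diff = beta - gamma
    # analytic limit (beta -> gamma): transient term beta*du0*tau*e^{-beta tau}
    near = np.isclose(beta, gamma, rtol=1e-12, atol=1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        trans = np.where(near, beta * du0 * tau * eb, beta * du0 * (eg - eb) / np.where(near, 1.0, diff))
    s = alpha / gamma + (s0 - alpha / gamma) * eg + trans
    return u, s


def steady_state(alpha, beta, gamma):
    """Fixed point (u*, s*) = (alpha/beta, alpha/gamma)."""
    alpha = np.asarray(alpha, float)
    return alpha / np.asarray(beta, float), alpha / np.asarray(gamma, float)


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass
class LineageTopology:
    """Latent time and branch assignment for every simulated cell."""

    t: np.ndarray
    branch: np.ndarray
    t_switch: float
    t_max: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.branch = np.asarray(self.branch, object)
        if self.t.shape != self.branch.shape:
            raise ValueError("t and branch must align")
        bad = set(np.unique(self.branch)) - set(BRANCHES)
        if bad:
            raise ValueError(f"unknown branch labels: {sorted(bad)}")
        if not 0 <= self.t_switch <= self.t_max:
            raise ValueError("t_switch must lie within [0, t_max]")
        pre = self.t < self.t_switch
        if (self.branch[pre] != PROGENITOR).any() or (self.branch[~pre] == PROGENITOR).any():
            raise ValueError("progenitor cells are exactly those with t < t_switch")

    @property
    def n_cells(self) -> int:
        return self.t.shape[0]


def sample_topology(n_cells, t_max, t_switch, p_branch_a=0.5, rng=None) -> LineageTopology:
    """Cells drawn uniformly on [0, t_max]; branches assigned after the switch."""
    rng = np.random.default_rng(rng)
    t = rng.uniform(0.0, t_max, size=n_cells)
    branch = np.full(n_cells, PROGENITOR, dtype=object)
    post = t >= t_switch
    a = rng.random(post.sum()) < p_branch_a
    branch[np.flatnonzero(post)[a]] = BRANCH_A
    branch[np.flatnonzero(post)[~a]] = BRANCH_B
    return LineageTopology(t=t, branch=branch, t_switch=t_switch, t_max=t_max)


def simulate_latent_kinetics(topology: LineageTopology, params: KineticParams,
                             initial_state: str | tuple = "steady"):
    """Latent (u, s) per cell per gene along the bifurcation.

    Progenitor cells evolve from the initial state under the progenitor
    rate; branch cells continue from the progenitor state at
    ``t_switch`` under their branch rate, so trajectories are continuous
    at the switch. ``initial_state`` is ``"steady"`` (the progenitor
    fixed point, the default) or an explicit ``(u0, s0)`` pair.

    Returns
    -------
    (U, S) : ndarray, cells x genes, non-negative.
    """
    if params.t_switch != topology.t_switch:
        raise ValueError("topology and params disagree on t_switch")
    G = params.n_genes
    if initial_state == "steady":
        u0, s0 = steady_state(params.alpha_progenitor, params.beta, params.gamma)
    else:
        u0, s0 = (np.broadcast_to(np.asarray(x, float), (G,)).copy() for x in initial_state)

    C = topology.n_cells
    U = np.empty((C, G))
    S = np.empty((C, G))

    # progenitor segment, evaluated at each cell's own time
    pre = topology.t < topology.t_switch
    if pre.any():
        tau = topology.t[pre][:, None]
        U[pre], S[pre] = kinetics_closed_form(u0, s0, params.alpha_progenitor,
                                              params.beta, params.gamma, tau)
    # state at the switch, shared by both branches
    u_sw, s_sw = kinetics_closed_form(u0, s0, params.alpha_progenitor,
                                      params.beta, params.gamma, topology.t_switch)
    for label, alpha in ((BRANCH_A, params.alpha_branch_a), (BRANCH_B, params.alpha_branch_b)):
        m = topology.branch == label
        if m.any():
            tau = (topology.t[m] - topology.t_switch)[:, None]
            U[m], S[m] = kinetics_closed_form(u_sw, s_sw, alpha, params.beta, params.gamma, tau)

    np.clip(U, 0.0, None, out=U)
    np.clip(S, 0.0, None, out=S)
    return U, S


# ---------------------------------------------------------------------------
# count sampling
# ---------------------------------------------------------------------------

def sample_counts(u_latent, s_latent, *, depth=5000.0, unspliced_depth_fraction=0.15,
                  dispersion=0.3, depth_sigma=0.25, rng=None,
                  var_names=None, obs_names=None, obs=None) -> VelocityDataset:
    """Draw integer counts from latent abundances.

    Each cell's latent profile is scaled to a lognormal sequencing depth
    (unspliced depth a fixed fraction of spliced, mimicking intronic
    capture); counts are gamma–Poisson (negative binomial with
    ``Var = mu + dispersion * mu^2``), reducing to Poisson at
    ``dispersion = 0``. Fully reproducible given ``rng``.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(rng)
    U = np.asarray(u_latent, float)
    S = np.asarray(s_latent, float)
    if U.shape != S.shape:
        raise ValueError("latent layers must share one shape")
    if (U < 0).any() or (S < 0).any():
        raise ValueError("latent abundances must be non-negative")
    C, G = S.shape

    depth_factor = np.exp(rng.normal(0.0, depth_sigma, size=C)) if depth_sigma > 0 else np.ones(C)

    def _draw(latent, layer_depth):
        rowsum = latent.sum(axis=1, keepdims=True)
        frac = np.divide(latent, rowsum, out=np.zeros_like(latent), where=rowsum > 0)
        mu = frac * (layer_depth * depth_factor)[:, None]
        if dispersion > 0:
            mu = mu * rng.gamma(shape=1.0 / dispersion, scale=dispersion, size=mu.shape)
        return rng.poisson(mu)

    spliced = _draw(S, depth)
    unspliced = _draw(U, depth * unspliced_depth_fraction)

    if var_names is None:
        var_names = [f"g{i:04d}" for i in range(G)]
    if obs_names is None:
        obs_names = [f"cell{i:05d}" for i in range(C)]
    if obs is None:
        obs = pd.DataFrame(index=pd.Index(obs_names, name="cell"))
    else:
        obs = obs.copy()
        obs.index = pd.Index(obs_names, name="cell")
    return VelocityDataset(
        spliced=sp.csr_matrix(spliced),
        unspliced=sp.csr_matrix(unspliced),
        var_names=pd.Index(var_names, name="gene"),
        obs=obs,
    )


# ---------------------------------------------------------------------------
# benchmark composition
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for the benchmark bifurcation.

    Defaults describe a desk-scale embryonic-head-like dataset: 3000
    cells over 1500 genes, 100 planted drivers, 10 regulons. Fold
    changes are the planted effect sizes of fate-commitment genes.
    """

    n_cells: int = 3000
    n_genes: int = 1500
    n_drivers: int = 100
    n_regulons: int = 10
    targets_per_regulon: int = 15
    n_signature: int = 10          # per compartment
    n_mito: int = 10
    n_cycle: int = 10
    t_max: float = 14.0
    t_switch: float = 6.0
    p_branch_a: float = 0.5
    driver_up_fold: float = 4.0
    driver_down_fold: float = 0.25
    signature_up_fold: float = 5.0
    signature_down_fold: float = 0.0   # shut-off programs go fully silent
    tf_coupling: float = 0.7       # weight of TF modulation on its targets
    tf_activity_sigma: float = 0.4  # per-cell lognormal activity of background TFs
    depth: float = 2000.0
    unspliced_depth_fraction: float = 0.15
    dispersion: float = 0.3
    depth_sigma: float = 0.25
    bad_cell_fraction: float = 0.05
    frac_plain_down: float = 0.3   # share of unnamed drivers that switch down

    def __post_init__(self) -> None:
        planted = (2 * self.n_signature + 4 + 1 + self.targets_per_regulon)
        if self.n_drivers and self.n_drivers < planted:
            raise ValueError(
                f"n_drivers={self.n_drivers} cannot hold the {planted} named planted genes"
            )
        budget = (self.n_drivers + self.n_regulons
                  + self.n_regulons * self.targets_per_regulon
                  + self.n_mito + self.n_cycle)
        if budget > self.n_genes:
            raise ValueError(f"planted sets ({budget} genes) exceed n_genes={self.n_genes}")


@dataclass
class SimulationTruth:
    """Planted ground truth — the oracle for recovery tests."""

    driver_genes: list
    regulon_map: dict
    signature_genes_myo: list
    signature_genes_nonmyo: list
    ligand_receptor_pairs: list      # (ligand, receptor, pathway, expected_sign)
    mito_fraction: pd.Series
    branch: pd.Series
    t: pd.Series
    t_switch: float
    branch_b_tf: str
    marker_config: dict
    params: KineticParams | None = None
    latent_u: np.ndarray | None = field(default=None, repr=False)
    latent_s: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if set(self.signature_genes_myo) & set(self.signature_genes_nonmyo):
            raise ValueError("signature gene sets must be disjoint")
        for tf, targets in self.regulon_map.items():
            if len(targets) < 5:
                raise ValueError(f"regulon {tf} has fewer than 5 targets")


def build_benchmark_dataset(config: SimConfig | None = None, seed: int | None = 0,
                            keep_latent: bool = True):
    """Compose the full benchmark: topology, kinetics, planted structure, counts.

    Returns ``(VelocityDataset, SimulationTruth)``. All randomness flows
    through ``seed``.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    G, C = cfg.n_genes, cfg.n_cells

    # ---- gene universe and planted roles -----------------------------------
    names = np.array([f"g{i:04d}" for i in range(G)], dtype=object)
    cursor = 0

    def take(n):
        nonlocal cursor
        idx = np.arange(cursor, cursor + n)
        cursor += n
        return idx

    idx_myo = take(cfg.n_signature) if cfg.n_drivers else take(0)
    idx_cnt = take(cfg.n_signature) if cfg.n_drivers else take(0)
    idx_lr = take(4) if cfg.n_drivers else take(0)       # LigMyo RecMyo LigNonmyo RecNonmyo
    idx_tfb = take(1) if cfg.n_drivers and cfg.n_regulons else take(0)
    idx_tfb_targets = take(cfg.targets_per_regulon) if len(idx_tfb) else take(0)
    n_plain = max(cfg.n_drivers - (len(idx_myo) + len(idx_cnt) + len(idx_lr)
                                   + len(idx_tfb) + len(idx_tfb_targets)), 0)
    idx_plain = take(n_plain)
    n_bg_tfs = max(cfg.n_regulons - len(idx_tfb), 0)
    idx_bg_tfs = take(n_bg_tfs)
    idx_bg_targets = take(n_bg_tfs * cfg.targets_per_regulon)
    idx_mito = take(cfg.n_mito)
    idx_cycle = take(cfg.n_cycle)

    for i, j in enumerate(idx_myo):
        names[j] = f"myo{i + 1:02d}"
    for i, j in enumerate(idx_cnt):
        names[j] = f"cnt{i + 1:02d}"
    if len(idx_lr):
        names[idx_lr] = ["LigMyo", "RecMyo", "LigNonmyo", "RecNonmyo"]
    tf_names = []
    for k, j in enumerate(list(idx_tfb) + list(idx_bg_tfs)):
        names[j] = f"TF{k + 1:02d}"
        tf_names.append(names[j])
    for i, j in enumerate(idx_mito):
        names[j] = f"mt-{i + 1:02d}"
    for i, j in enumerate(idx_cycle):
        names[j] = f"ccl{i + 1:02d}"

    # ---- kinetic parameters -------------------------------------------------
    base = np.exp(rng.normal(0.0, 0.5, size=G))
    beta = np.ones(G)
    gamma = rng.uniform(0.4, 1.0, size=G)  # decay fast relative to lineage progression

    a_prog = base.copy()
    a_prog[idx_myo] *= 3.0          # myogenic program on in progenitors
    # the non-myogenic program is near-silent before commitment
    off_in_prog = np.concatenate([idx_cnt, idx_lr[2:]]) if len(idx_lr) else idx_cnt
    a_prog[off_in_prog] = base[off_in_prog] * 0.05
    if len(idx_lr):
        a_prog[idx_lr[0]] *= 3.0    # LigMyo expressed like the myogenic program

    a_a = a_prog.copy()
    a_b = a_prog.copy()
    # myogenic side: stays on in branch A, shuts off in branch B
    down_sig = np.concatenate([idx_myo, idx_lr[:1]]) if len(idx_lr) else idx_myo
    a_b[down_sig] *= cfg.signature_down_fold
    if len(idx_lr):
        a_a[idx_lr[1]] *= 3.0                       # RecMyo up in branch A
        a_b[idx_lr[1]] *= cfg.driver_down_fold      # ... down in branch B
    # non-myogenic side: switches on (from near-silence) in branch B only
    up_sig = off_in_prog
    a_b[up_sig] = base[up_sig] * cfg.signature_up_fold
    # branch-B TF switches on; its targets follow through coupling below
    a_b[idx_tfb] *= cfg.driver_up_fold
    # plain drivers: mixed up/down switches in branch B
    n_down = int(round(cfg.frac_plain_down * len(idx_plain)))
    a_b[idx_plain[: len(idx_plain) - n_down]] *= cfg.driver_up_fold
    a_b[idx_plain[len(idx_plain) - n_down:]] *= cfg.driver_down_fold

    params = KineticParams(alpha_progenitor=a_prog, alpha_branch_a=a_a,
                           alpha_branch_b=a_b, beta=beta, gamma=gamma,
                           t_switch=cfg.t_switch)

    # ---- latent kinetics ----------------------------------------------------
    topo = sample_topology(C, cfg.t_max, cfg.t_switch, cfg.p_branch_a, rng)
    U, S = simulate_latent_kinetics(topo, params)

    # regulon coupling: target output scaled by its TF's latent expression
    regulon_map: dict[str, list] = {}
    tf_all = list(idx_tfb) + list(idx_bg_tfs)
    target_blocks = ([idx_tfb_targets] if len(idx_tfb) else []) + [
        idx_bg_targets[k * cfg.targets_per_regulon:(k + 1) * cfg.targets_per_regulon]
        for k in range(n_bg_tfs)
    ]
    branch_b_tf_idx = idx_tfb[0] if len(idx_tfb) else None
    for j_tf, block in zip(tf_all, target_blocks):
        if j_tf != branch_b_tf_idx and cfg.tf_activity_sigma > 0:
            # background TFs vary cell-to-cell through a latent activity factor
            act = np.exp(rng.normal(0.0, cfg.tf_activity_sigma, size=C))
            U[:, j_tf] *= act
            S[:, j_tf] *= act
        tf_s = S[:, j_tf]
        mod = (1.0 - cfg.tf_coupling) + cfg.tf_coupling * tf_s / max(tf_s.mean(), 1e-12)
        U[:, block] *= mod[:, None]
        S[:, block] *= mod[:, None]
        regulon_map[names[j_tf]] = list(names[block])

    # cell-cycle-like covariate acting on a small gene module
    cc_score = rng.normal(0.0, 1.0, size=C)
    if len(idx_cycle):
        fac = np.exp(0.5 * cc_score)
        U[:, idx_cycle] *= fac[:, None]
        S[:, idx_cycle] *= fac[:, None]

    # mitochondrial load: planted per-cell fraction, incl. a bad subpopulation
    mito_frac = rng.beta(2.0, 23.0, size=C)
    bad = rng.random(C) < cfg.bad_cell_fraction
    mito_frac[bad] = rng.uniform(0.25, 0.5, size=bad.sum())
    if len(idx_mito):
        other = np.delete(np.arange(G), idx_mito)
        for M in (U, S):
            tot = M[:, other].sum(axis=1)
            share = mito_frac / (1.0 - mito_frac) * tot / len(idx_mito)
            w = rng.dirichlet(np.full(len(idx_mito), 20.0), size=1)[0]
            M[:, idx_mito] = share[:, None] * (w * len(idx_mito))[None, :]

    # ---- counts + metadata --------------------------------------------------
    obs = pd.DataFrame({
        "cluster": topo.branch,
        "latent_time": topo.t,
        "cc_score": cc_score,
    })
    ds = sample_counts(U, S, depth=cfg.depth,
                       unspliced_depth_fraction=cfg.unspliced_depth_fraction,
                       dispersion=cfg.dispersion, depth_sigma=cfg.depth_sigma,
                       rng=rng, var_names=list(names), obs=obs)
    spl = np.asarray(ds.spliced.sum(axis=1)).ravel()
    ds.obs["total_counts"] = spl
    ds.obs["n_genes"] = np.asarray((ds.spliced > 0).sum(axis=1)).ravel()
    mito_cols = ds.var_names.str.startswith("mt-")
    mito_counts = np.asarray(ds.spliced[:, np.flatnonzero(mito_cols)].sum(axis=1)).ravel()
    ds.obs["mito_fraction"] = np.divide(mito_counts, spl, out=np.zeros(C), where=spl > 0)

    driver_idx = np.flatnonzero(params.alpha_branch_b != params.alpha_progenitor)
    driver_idx = np.union1d(driver_idx, idx_tfb_targets)  # coupled targets switch too
    pairs = ([("LigMyo", "RecNonmyo", "Pdgf", +1), ("LigNonmyo", "RecMyo", "Bmp", -1)]
             if len(idx_lr) else [])
    truth = SimulationTruth(
        driver_genes=list(names[driver_idx]),
        regulon_map=regulon_map,
        signature_genes_myo=list(names[idx_myo]),
        signature_genes_nonmyo=list(names[idx_cnt]),
        ligand_receptor_pairs=pairs,
        mito_fraction=pd.Series(mito_frac, index=ds.obs_names),
        branch=pd.Series(topo.branch, index=ds.obs_names),
        t=pd.Series(topo.t, index=ds.obs_names),
        t_switch=cfg.t_switch,
        branch_b_tf=(names[idx_tfb[0]] if len(idx_tfb) else ""),
        marker_config={
            "ligand_marker": "LigMyo" if len(idx_lr) else "",
            "receptor_marker": "RecNonmyo" if len(idx_lr) else "",
            "myogenic_genes": list(names[idx_myo[:3]]),
        },
        params=params,
        latent_u=U if keep_latent else None,
        latent_s=S if keep_latent else None,
    )
    return ds, truth
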