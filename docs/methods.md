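# Methods

## Model and pipeline

`drivereg` analyses a bifurcating developmental lineage — a shared
progenitor state splitting into a myogenic and a non-myogenic
(connective-tissue) fate — from paired spliced/unspliced single-cell
count matrices. The underlying kinetic model per gene is the standard
two-species splicing system

    du/dt = α − β·u        ds/dt = β·u − γ·s

with transcription rate α (molecules per unit time), splicing rate β
and degradation rate γ (both per unit time). At transcriptional
equilibrium u = (γ/β)·s; the per-gene estimator γ̂ is the
zero-intercept least-squares slope of u on s restricted to the cells in
the lower and upper `extreme_quantile` (default 0.05 per tail) of
spliced abundance, where equilibrium holds best. Velocity is
v = u − γ̂·s on kNN-smoothed, depth-normalized abundances; its sign is
the direction of transcriptional change. This is the steady-state
formulation; the EM-based "dynamical" likelihood model of upstream
tools is deliberately not re-implemented. Driver genes — the
transcriptomically active genes of a cluster — are therefore defined by
an explicit, testable score rather than a tool-internal likelihood:

    driver_score = fit_r2 × normalized dynamic range

where `fit_r2` is the R² of a two-segment piecewise-linear fit to the
cluster's phase portrait (segments assigned by the sign of u − γ̂·s,
i.e. induction vs repression) and the normalized dynamic range is the
relative contrast (q95 − q5)/(q95 + q5) of smoothed spliced abundance,
in [0, 1]. The contrast normalization is per gene and scale-invariant:
a highly expressed but static gene scores ≈ 0, a gene sweeping from
silence to its maximum scores ≈ 1. (An earlier share-of-maximum
normalization let flat, highly expressed genes ride compositional
depth drift into the top of the list; the relative contrast removes
that artifact.) Equivalence with any particular upstream tool's
ranking is not claimed — correctness is asserted as recovery of
planted ground truth. Mitochondrial (`mt-*`) genes are excluded from
driver ranking, as is standard in velocity workflows. The cluster must
have ≥ 20 cells; genes need ≥ 10 expressing cells and a positive slope
to be fit. Differential-kinetics correction for outlier genes is out
of scope.

Velocity confidence per cell is the mean cosine similarity between its
velocity vector and its neighbours' — high inside committed domains,
low at the branchpoint where neighbours head to different fates.

## Signatures, transition cells, regulons, networks

Compartments are annotated by a marker rule on raw counts: a cell is
myogenic iff it has any count of the ligand marker (Pdgfa-like) or of
any canonical myogenic gene (Myf5/Myod/Myog-like); otherwise
non-myogenic. Markers per compartment are ranked by a two-sided
Wilcoxon rank-sum (tie-corrected normal approximation) with positive
log fold change, ranked by p then fold change; the top 10 define each
signature. Signature sums are taken over normalized log expression
(not raw counts — the signatures follow the normalized workflow; a
raw-count option exists), normalized to fractions s_m + s_n = 1, and
the coexpression score c = s_m·s_n ∈ [0, 0.25] flags transition cells
strictly above the 0.20 threshold ("more than" read as strict
inequality; likewise the mito QC cutoff discards cells strictly above
0.20). Cells silent for both signatures are reported missing rather
than set to 0.5/0.5, which would fabricate maximal coexpression from
silence. For display, cells are ordered by s_n ascending with a stable
tie-break on the cell identifier.

Regulon activity is AUCell-style: per cell, genes are ranked by
descending expression with a deterministic tie-break on gene order
(reproducibility over randomized tie-breaking); the recovery curve
counts regulon targets within the top `top_fraction` (default 0.05) of
ranks; the AUC is normalized by the maximum achievable area. The
statistic for "most active in a cluster" is the difference of mean AUC
(cluster vs rest); a Mann–Whitney U and p-value are reported alongside
but do not drive the ranking. Regulon discovery is consumed as input
(GMT); a correlation-threshold builder exists only to make test
regulons from synthetic data.

The driver-regulator network links each active TF to the driver genes
among its regulon targets; any TF with ≥ `min_driver_targets`
(default 1) links is a driver regulator of that dataset. "Start of the
non-myogenic trajectory" is operationalized as the non-myogenic
cluster's cells in the lowest tercile of s_n (configurable). Extended
(lower-confidence) regulons are included and flagged. Cross-dataset
recurrence is the row sum of the binary TF × dataset presence matrix.

Ligand–receptor complementarity translates an imaging area-ratio
readout to expression: per gene, log2((mean_myo + ε)/(mean_nonmyo + ε))
with pseudocount ε = 0.01; the pair score subtracts the receptor's
ratio from the ligand's, making the score exactly antisymmetric under
swapping the compartments. Only signs are interpreted.

## Synthetic benchmark: what it emulates, and what it does not

The generator draws cell times uniformly on [0, T] (T = 14); cells
before t_switch = 6 are progenitors (initialised at the progenitor
fixed point), later cells continue the closed-form kinetics under a
branch-specific α (branch A : branch B = 50 : 50), continuous at the
switch. Planted structure, all recorded in `SimulationTruth`:

* **100 driver genes** — genes whose effective branch-B transcription
  rate differs from the progenitor rate: up-switches (×4), down-
  switches (×0.25), the 10 non-myogenic signature genes (near-silent
  baseline ×0.05 of their base rate, switching to ×5), the 10 myogenic
  signature genes (×3 baseline, fully silenced in branch B — a shut-off
  fate program goes to zero, as Myf5/Myod/Myog do in connective
  tissue), two ligand–receptor pairs with opposite compartment bias,
  the branch-B TF (×4) and its 15 coupled targets.
* **10 regulons** of 15 targets each; target output is scaled by the
  TF's own latent expression (coupling weight 0.7), background TFs vary
  through a per-cell lognormal activity (σ = 0.4).
* **Mitochondrial load**: 10 `mt-*` genes with per-cell planted
  fractions from Beta(2, 23) plus 5% "bad" cells at U(0.25, 0.5), so
  the QC filter has real work.
* **Counts**: gamma–Poisson (negative binomial, Var = μ + 0.3·μ²) with
  lognormal per-cell depth (σ = 0.25), spliced depth 2000 over 1500
  genes and unspliced depth 15% of spliced (intronic capture). Depth
  was chosen so per-gene sparsity matches droplet data — with mean
  counts per gene well above 1 there is effectively no dropout and a
  count-positivity annotation rule degenerates.
* **Kinetics**: β = 1 (rates expressed relative to splicing),
  γ ~ U(0.4, 1.0) — mRNA turnover fast relative to lineage progression,
  so committed cells approach their new equilibrium and shut-off
  programs actually empty.

Not emulated: batch effects, ambiguous reads, doublets, a fitted noise
model from any real deposit, multi-branch topologies. Passing tests
therefore demonstrate correctness of the algorithms under a faithful
generative model of the assumed kinetics and noise — not performance
on real embryonic data, where kinetic heterogeneity, shared regulons
and annotation ambiguity are harsher.

## Numerical choices and degenerate inputs

The closed form handles β = γ by its analytic limit (β·Δu·τ·e^(−βτ)).
The β = γ branch switches at |β − γ| ≤ 1e-12 relative. All-zero genes
and under-expressed genes are flagged unfit and excluded from velocity.
A two-segment fit with a degenerate segment (< 2 cells or zero spread)
falls back to the segment mean; R² is clipped to [0, 1], and is 0 for
constant genes (zero total variance). Zero-velocity cells score 0 in
the velocity graph and are missing (NaN) in confidence. OLS covariate
regression restores the intercept so gene means are preserved, and
rejects rank-deficient designs naming the collinear columns.
Rank-deficient PCA inputs are handled by capping n_pcs. kNN excludes
self even under exact-duplicate ties. Default problem sizes (3000
cells, 1500 genes; five seeds for recovery statistics, four runs for
recurrence, three seeds in the acceptance script) are desk-scale
choices giving stable recovery statistics at interactive runtimes.

## Known limitations

* The steady-state γ̂ is biased when a cluster never reaches
  equilibrium; the extreme-quantile restriction mitigates but does not
  remove this.
* The driver score is a proxy for "best-explained dynamic gene"; genes
  with coordinated non-kinetic variation (e.g. strong regulon coupling
  without a rate switch) can enter the list.
* The compartment rule depends on count positivity and hence on
  sequencing depth; at high depth per gene it saturates toward
  "myogenic" unless markers are truly silent.
* Recurrence treats datasets symmetrically and unweighted; a TF found
  in four shallow runs counts the same as one found in four deep runs.
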