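# Methods

This note documents the models implemented in `popclock`, their
assumptions, the defaults that matter, and the numerical choices made
where the design was genuinely open.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The bulk-referenced time model

**Assumptions.** A differentiation time course has been measured in
bulk (cell-population) RNA-seq at known collection times, and in
scRNA-seq on the same process.  The bulk samples are treated as a
low-noise average over a large population, so their transcriptomes are
a smooth function of time; single cells are assumed to sit on the same
expression manifold, displaced mainly along time (differentiation
speed heterogeneity) plus measurement noise and dropout.  Expression
is compared on the log₁₀(RPKM+1) scale throughout.

**Preprocessing.** Single-cell matrices are quantile-normalized
(bulk matrices pass through unchanged unless requested), then filtered
to genes with RPKM > 0.5 (strict) in at least 8 cells, then
log-transformed.  Ties in quantile normalization take the mean of the
reference values over the tied rank span; this preserves within-column
order and column sums but — unavoidably — sacrifices exact multiset
equality and idempotence on tied columns (both hold exactly for
tie-free columns, and are tested in that regime).

**Fitting.** Genes are restricted to (bulk differential genes) ∩
(single-cell-expressed genes).  When no external differential gene
list is supplied, bulk "differential" genes are taken as genes
time-correlated in bulk (|PCC| ≥ 0.6, randomization p ≤ 0.003 with
1000 permutations); rank-product DE between stages is available as an
alternative.  Genes are centred and z-scored (flag `scaled`,
default on) before a two-component PLS1 (NIPALS, X-deflation only)
against the centred collection-time vector.  Scores are expressed
through the rotation `R = W(PᵀW)⁻¹` so they are linear in the
*original* centred matrix — this is what makes single-cell transfer a
plain projection; for the first component the rotation equals the
weight vector `w₁ ∝ Xᵀy` exactly.  Component signs are oriented so
each score correlates non-negatively with time (PLS signs are
arbitrary).  Time is then regressed on the two scores by OLS.

**Transfer and calibration.** Cells are projected through the stored
centres, scales and rotation; model genes missing from the single-cell
matrix are imputed at the training centre (zero contribution, count
warned).  The batch offset between modalities is removed by one shared
linear map: raw model time is regressed on the cells' collection times
(`raw_T = a′·time + b′`) and inverted, giving `t = raw_T/a′ − b′/a′`
on the real time axis.  Degenerate cases: a single shared collection
time skips calibration (identity map, warning); |a′| below 1e-12
falls back to a mean-offset shift.

**Timer genes.** Per-gene Pearson correlation with `T` (bulk) or `t`
(single cells), with a two-sided sample-randomization p-value
`(1 + #{perm : |PCC| ≥ |obs|})/(n_perm + 1)`; all permutations are
enumerated when `n! ≤ n_perm` (then the exact fraction is used — the
identity permutation counts, so p is never 0).  Selection requires
*both* the |PCC| cutoff and the p cutoff (0.6/0.003 bulk, 0.4/0.001
single-cell, 0.05 for per-stage sets); the cutoff pairs correspond
only at particular sample sizes, so the conjunction is enforced rather
than either criterion alone.

**Branches.** Cells are displayed in the plane (t, scPLS2): the second
score captures the largest expression variance not already aligned
with predicted time, so diverging lineages separate along it.  The
late-time half of cells is clustered in scPLS2 by k-means with
k ∈ {1,2,3} chosen by silhouette.  The silhouette floor for accepting
k > 1 is 0.75: one-dimensional k-means on unimodal noise already
reaches silhouettes near 0.55 (measured 0.54–0.62 on Gaussian and
uniform samples), while genuinely separated branches score above 0.8,
so a low floor would split every trajectory.

## Sampling saturation

For each subset size k ∈ 1..n, min(C(n,k), 30) distinct cell subsets
are drawn (all combinations are enumerated when C(n,k) is below the
cap, removing Monte-Carlo noise at the extremes); the subset-average
profile is correlated (Pearson, log scale) with the matched bulk
reference, restricted to genes averaging > 0.5 in the subset *or*
> 0.5 in the reference (the union keeps the gene set comparable on
both sides; `gene_filter` exposes the single-cell-only and no-filter
variants).  Because the log transform breaks scale invariance, a
reference constructed as a ratio-weighted *sum* of cell profiles must
be divided by the total ratio weight (`reference_scale`) to land on
the per-cell scale; the full weighted multiset then reproduces the
reference exactly (PCC = 1 to machine precision).  The saturation
point is the smallest k whose mean PCC is within ε (default 0.01, a
declared default, not an empirical constant) of the full-sample value.

## Flow networks

Sources (bulk-expressed, single-cell-undetected time genes) and
targets (single-cell timer genes of the flanking stages) are joined
through an undirected PPI template (union of edge files; score-bearing
edges kept at score > 600; duplicate edges keep the maximum
confidence).  Template edges are weighted by |PCC| over the bulk
samples of the stage transition window; zero-weight or constant-gene
edges are dropped.  Each undirected edge becomes two antiparallel
unit-capacity arcs with cost −log w; a super-source feeds all sources
and all targets drain to a super-sink through free unit arcs.  The
continuous LP

    min Σ f_e·(−log w_e) − γ·(flow out of S)

is solved with HiGHS (`scipy.optimize.linprog`); fractional flow keeps
the solution deterministic, and unit capacities bound the program for
any γ.  Edges carrying flow above 1e-6 form the selected subnetwork.
γ is chosen over a user grid; the default scorer returns the largest
network whose minimum selected-edge weight exceeds 0.6, and a
literature-based scorer (e.g. a co-citation index) can be injected as
a callback instead — no literature database access is built in.  Hubs
are nodes with degree strictly > 4 in the selected subnetwork, capped
to the top 5% of nodes by degree when that cap binds (boundary ties
included); the degree rule and the percentile rule are enforced
conjunctively and this reading is recorded in the output metadata.

## CSI networks

For a gene set G with absolute correlation matrix P over a transition
window, CSI(A,B) is the fraction of third-party genes C (C ∉ {A,B})
with P(A,C) < P(A,B) − m and P(B,C) < P(A,B) − m, with margin
m = 0.05 and denominator |G| − 2; both the margin and the
strict-inequality convention are config-exposed since published CSI
variants differ.  Self-pairs have no meaning under this definition
(the two exclusions coincide and the ratio can exceed 1), so the
diagonal is fixed at 0; edges keep pairs with CSI > 0.6.  Transition
networks are merged by edge union, keeping the maximum CSI for
duplicates, with per-node stage labels taken from the stage in which
the node's pathway is activated.

## Enrichment machinery

*Overlap tests* are one-sided hypergeometric tails with Bonferroni
correction across the terms tested in the call; the default universe
is the measured gene universe of the input matrix (a pragmatic proxy
for "the whole genome", configurable).  *GSEA* uses the weighted
Kolmogorov–Smirnov running sum (hit steps ∝ |score|^w, w = 1 by
default; w = 0 makes the score rank-only) with a gene-set permutation
null — sample permutation is impossible on a single ranked list — and
a same-sign NES/FDR normalization.  The activation call for a pathway
in a stage is the conjunction: members Fisher-enriched in the
stage-specific gene set (Bonferroni p < 0.05) AND upregulated targets
positively GSEA-enriched in the stage's expression ranking
(FDR < 0.05 by default; the threshold is a config value because
reasonable published choices range up to 0.25).  Pathways without a
target set are reported untestable, never inactive.

*Rank-product DE* ranks fold changes per replicate pair and takes the
geometric mean of ranks; the null permutes values within genes, and
counting is done on the product-of-ranks scale where (half-)integer
products are exact floats, so observed-vs-null ties resolve
deterministically.  An exhaustive mode enumerates the iid-uniform rank
grid exactly for small problems.  Two quantities are reported: the
classical pfp (expected false positives at the gene's rank — near 1
for every gene under a complete null, as an FDR-type quantity should
be) and a per-gene permutation p-value, which is the uniform-calibrated
quantity.  The permutation null treats replicate ranks as independent,
which is exact for paired designs (`pairing="paired"`); with all-pairs
replication the pairs share samples and the p-values become
conservative approximations.

*Network interaction tests* count edges between two gene sets and
compare against same-size node sets redrawn from the universe, with
p = (1 + #{perm ≥ obs})/(n_perm + 1).  The count statistic is
discrete, so this p-value is conservative (super-uniform) under the
null; `randomized=True` breaks ties with an auxiliary uniform draw
(p = (#{>} + U·(1 + #{=}))/(n_perm+1)), which is exactly uniform and
is what the calibration checks use.  The conservative default is the
right choice for reporting discoveries.

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions the package is validated
under:

* **Trajectory** (`TrajectorySimSpec`): 8 timepoints spanning 0–14 h
  (2 h spacing, 4 stages), 3 bulk replicates and 8 cells per
  timepoint, 2000 genes with 300 timer genes.  Timer genes follow
  monotone functions of time — affine by default; a `sigmoid_fraction`
  of logistic-shaped genes is available — with additive Gaussian noise
  of sd = `noise_sd` × the gene's signal sd (default 0.3) and optional
  magnitude-dependent dropout (`p = rate·exp(−x/median)`).  Cells draw
  a latent time from a truncated Gaussian jitter (sd = ¼ timepoint
  spacing) around their collection time, so "collection time" and
  "true time" differ per cell, as in a real asynchronous culture.  The
  affine default is what makes the noiseless limit exactly recoverable
  (every timer gene has |PCC| = 1 with time and the fitted clock is
  affine in time).
* **Subtypes** (`SubtypeSimSpec`): hierarchical gamma–Poisson counts —
  gene means Gamma(0.6, 2), lognormal(0, 0.35) library sizes,
  sign-symmetric lognormal(0.1, 0.4) DE factors applied to a 20%
  gene subset per subtype; subtype counts follow largest-remainder
  rounding of the requested proportions (a 5% rare type among 20,000
  cells is exactly 1000 cells).  These hyperparameters are a standard
  gamma–Poisson hierarchy, config-exposed, not claimed to match any
  particular dataset.
* **Expansion** (`ExpansionSimSpec`): two subpopulations distinct in
  20% of genes; five timepoints; at each transition a further 1% of
  genes shift log-linearly in *both* populations (the shared temporal
  signal, effect scale 1.5 on the log scale — chosen so that the
  balanced control recovers minor-population order with rank
  correlations around 0.8–0.93, i.e. the regime where the expansion
  effect is a degradation of good recovery rather than noise on
  noise); the expanding population's proportion follows a geometric
  schedule between the stated endpoints (0.5 → 0.95), and matched
  bulk profiles are composition-weighted sums.  The degradation
  mechanism is identity confounding: under expansion the 20%
  population-identity genes acquire a time trend in bulk, the clock
  loads on them, and minor-population cells — whose identity genes do
  not move — lose their ordering.
* **Mixtures / downsampling**: ratio-weighted sums of single-cell
  profiles and multinomial read resampling at a chosen depth (read
  mass ∝ RPKM × gene length, default 1 kb constant lengths).

Not emulated: UMI counting, doublets, ambient RNA, batch structure
beyond the single linear bulk-to-cell offset, realistic gene-length
distributions, and cell-cycle oscillations superimposed on the
trajectory.  Passing tests therefore demonstrate correctness of the
algorithms under the stated generative assumptions, not robustness to
every artefact of real scRNA-seq.

## Problem sizes and determinism

All randomized components take explicit seeds and are bit-reproducible;
the pipeline derives per-stage seeds from a master seed by hashing the
stage name, so toggling one stage never shifts another's randomness,
and a run can be reproduced byte-identically from its manifest alone.
The standard validation sizes are: 2000 genes × 64 cells for the
recovery experiments (5 seeds for the noisy and expansion studies);
20 random ≤ 12-node instances for the flow-solver oracle; 25 genes ×
10 seeds for the CSI oracle; 300–500 replicates for the calibration
checks (999 and 99 permutations respectively); and an exhaustive
N = 20 grid for the hypergeometric oracle.  These sizes give stable
checks while keeping the full suite and the acceptance script fast on
a single CPU.
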