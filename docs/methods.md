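# Methods

This note documents the models implemented in `connstrat`, the
assumptions behind them, the defaults and why they were chosen, and
what the synthetic benchmarks do and do not demonstrate.

## Connectome construction

Per-subject regional time series (T × N, no missing values) pass
through a fixed order of operations: confound regression → band-pass →
Pearson correlation → threshold → Fisher z. The order matters:
filtering after regression avoids re-introducing confound energy into
the pass band, and thresholding operates on correlations, not z-values.

- **Confound regression** is ordinary least squares against the supplied
  confound columns plus an intercept; outputs are exact residuals, so
  every output column is orthogonal to every confound. The intended
  nuisance set is the global signal plus six motion parameters (k = 7),
  but any full-rank T × k matrix is accepted.
- **Band-pass** is a 2nd-order Butterworth with zero-phase
  forward–backward application (`sosfiltfilt`), pass band 0.01–0.1 Hz
  by default. The filter family is a package choice — standard
  resting-state practice — since only the band is externally specified.
  With 256 volumes at TR = 2 s, a 0.05 Hz signal retains ≥ 90% amplitude
  and a 0.24 Hz signal is attenuated below 10%, measured in steady state
  (the forward–backward pass has edge transients over roughly the first
  and last 30 samples; amplitude ratios are evaluated on the central
  portion).
- **Threshold + Fisher z**: edges with r ≥ 0.2 are retained and mapped
  by atanh; everything else, including every negative correlation, is
  zeroed. The retention rule is deliberately signed — taking |r| would
  change the meaning of the threshold. Ties at exactly 0.2 are retained.
  Re-applying the operation to its own output preserves the zero/support
  pattern (atanh is increasing and atanh(z) > z for z > 0) but not the
  retained values; the pipeline never does this.

Edges are indexed by the strict upper triangle in lexicographic order,
0-based; N regions give N(N−1)/2 possible connections (69 751 at
N = 374, the scale of an HCP-MMP cortical parcellation plus 16
subcortical regions).

## Consensus clustering

The stratification pipeline clusters subjects, not regions. Inputs are
z-scored behavioural features (mean 0, sample SD 1; constant or missing
features are rejected — imputation is out of scope).

**Affinity kernel.** W(i,j) = exp(−d²(i,j) / (2 (α ε(i,j))²)), with
ε(i,j) the average of three terms: the mean distance from i to its K
nearest neighbours, the same for j, and d(i,j). This is the locally
scaled Gaussian kernel familiar from similarity-network-fusion
toolkits, without the Gaussian density normalizing constant, which
cancels in normalized spectral clustering. K controls how local the
scale is (larger K → denser effective graphs), α scales the kernel
width (larger α → weaker edges survive). Defaults K ∈ {10,15,20,25,30},
α ∈ {0.3,…,0.8} — the 30-combination grid the pipeline searches.

**Spectral clustering.** Embedding by the C eigenvectors of the
symmetric normalized Laplacian L = I − D^(−1/2) W D^(−1/2) belonging to
the smallest eigenvalues, rows normalized to unit length, followed by
seeded k-means (scipy `kmeans2`, ++ initialization, 3 restarts, best
inertia kept). Restart count is small because the embedding of a
C-clusterable affinity matrix is nearly ideal for k-means; the restart
stream derives from the caller's generator, so results are reproducible
at any parallelism. If every restart collapses (degenerate embeddings
of pathological inputs), a deterministic rank split of the Fiedler
coordinate is used instead.

**Nested consensus.** Each grid point runs `n_bootstrap` resamples
(default 1000): an 80% subject subsample *without replacement*, spectral
clustering of the induced subnetwork, and accumulation of
co-memberships. co_cluster(i,j) is the fraction of resamples containing
both i and j that cluster them together; pairs never co-sampled are
reported and scored 0. Final labels per grid point cut the average-
linkage tree of 1 − co_cluster at C (`cut_tree`, which always yields
exactly C groups even with tied merge heights). Item resampling without
replacement is the default of the consensus tooling this emulates;
with-replacement bootstrap is a one-line change if needed.

**Grid selection and outer loop.** The grid point with the highest mean
silhouette wins; ties break toward smaller K, then smaller α
(deterministic). The whole selection is repeated `n_repeats` times
(default 1000) on random 80% subsamples of the cohort, winning labels
accumulate into the outer consensus matrix, and the final partition is
again an average-linkage cut. One master seed spawns independent
per-repeat streams.

**Silhouette basis.** By default the silhouette is computed on
consensus dissimilarity (1 − co_cluster): it scores the quantity the
final labels actually partition. This measures *stability*, and that
has a consequence worth knowing: on structure-free data, spectral
splits of a fixed noise sample are themselves reproducible across 80%
subsamples, so the consensus silhouette can stay high (~0.6) under the
null. A high consensus silhouette therefore means "this split is
stable", not "this split reflects real geometry". The
`silhouette_basis="euclidean"` option scores the same labels on the
feature-space distances instead; under the null that value is low
(< 0.3 at n = 156), and the degenerate-null regression test asserts it
on that basis.

**Cluster number.** Two criteria on the normalized Laplacian of a
similarity network, over candidates 2…10 by default: (i) eigengap — C
maximizing λ_{C+1} − λ_C (ascending eigenvalues); (ii) rotation cost —
C minimizing a row-concentration cost of the spectral embedding after
rotating it toward the nearest cluster-indicator matrix (alternating
argmax assignment and orthogonal Procrustes, a Yu–Shi style
discretisation). The rotation-cost reference implementation lives in an
R package whose exact discretisation is not published prose; ours is
validated behaviourally — both criteria recover planted block counts
and blob counts in simulation — rather than bit-for-bit. Ties prefer
smaller C.

## Network Based Statistic

**Edgewise model.** For each of the N(N−1)/2 edges, OLS of the Fisher-z
weight on intercept + group indicator + covariates (mean framewise
displacement, sex, age, ordinal SES by default); t = β̂/SE with
df = n − p. The implementation is a single vectorized solve across all
edges and matches a per-edge regression oracle to 1e−8. Edges with
numerically zero residual variance get t = 0. SES strings are coded
ordinally (I–II = 1, III = 2, IV–V = 3); other codings can be supplied
as numeric columns.

**Thresholding and components.** One-sided retention at the NBS
threshold (t ≥ t₁₋ₚ,df for the tested direction; 0.05, 0.01, 0.001 are
the conventional choices, 0.01 the default). Connected components of
the supra-threshold graph are scored by strength (Σt over the
component's edges); extent (edge count) is available as an alternative
statistic. Per-node connection shares within a component
(`nodal_degree_percent`) identify component "hubs".

**Permutation inference.** The null distribution of the maximum
component statistic is built by Freedman–Lane permutation: the reduced
(covariate-only) model is fitted once, its residuals are row-permuted,
refitted under the full model, and the maximum supra-threshold
component strength recorded. p_FWER = (1 + #{null max ≥ observed}) /
(1 + n_perm), bounded below by 1/(n_perm+1). Freedman–Lane is the
default because the nuisance covariates are genuinely confounded with
group (head motion differs between groups by construction in the
synthetic cohorts, as it does in real preterm cohorts); naive label
shuffling (`perm_scheme="labels"`) is available for comparison. With
200 permutations and α = 0.05, the empirical family-wise error over
200 synthetic null datasets is 0.050–0.065 depending on seed — inside
the 95% binomial interval [0.020, 0.080].

**Interactions.** The factorial design group + subgroup +
group×subgroup (plus covariates) tests the interaction coefficient in
both tails; on additive-only synthetic data the interaction contrast is
significant in ≲5% of runs.

## Overlap and behavioural statistics

Sørensen–Dice 2k/(|A|+|B|) for node sets and edge sets (0 for two empty
sets); edge-overlap significance is the upper hypergeometric tail over
the universe of possible connections, exact and symmetric in the two
sets, verified against exhaustive enumeration for universes ≤ 12.
Reported coefficients are rounded to 2 decimals; full precision is kept
internally. Note that for set sizes (962, 832) with 22 shared edges the
formula gives 0.02 at two decimals.

Behavioural comparisons: Mann–Whitney rank-sum (asymptotic, tie
corrected, no continuity correction by default) with rank-biserial
r = 2U/(n₁n₂) − 1, oriented so positive means the first-listed sample
tends larger; χ² (no Yates correction) with Cramér's V, switching to
Fisher's exact for 2×2 tables with any expected count < 5; BH step-up
FDR; and covariate-adjusted sensitivity tests by Freedman–Lane
permutation of the group coefficient's t (default 5000 permutations).
The summary table reports both raw-FDR and adjusted-FDR columns
(adjust-then-FDR order).

## Synthetic cohorts

The generator emulates the structure of an adult VPT/FT follow-up
cohort: n = 156 subjects, 13 standardized behavioural features, an
85/71 latent subgroup split, VPT fraction 85/156, age ≈ 30 ± 3.5 years,
group-specific sex ratios, 3-level ordinal SES, and log-normal
framewise displacement with medians 0.15 mm (VPT) vs 0.12 mm (FT) —
i.e. the motion–group confound is built in so that covariate-adjusted
inference is actually exercised. Subgroup membership is independent of
clinical group. Feature noise is unit-variance Gaussian per subgroup;
planted effects are additive mean shifts in d units.

Connectome stacks place U(0.2, 0.6) baseline weights on every edge
(plausible retained Fisher-z values) with between-subject SD 0.2
z-units, and shift a planted edge set by ±δ/2 per group. The planted
set is grown by random breadth-first expansion from anchor seeds, which
guarantees topological connectedness and mimics hub-anchored
components. Time series are multivariate Gaussian with block covariance
following a supplied partition (256 volumes at TR = 2 s by default).

What passing these benchmarks shows: the machinery is calibrated and
recovers planted structure under Gaussian noise at realistic sample
sizes. What it does not show: robustness to heavy-tailed behavioural
distributions, missing data, site effects, spatial autocorrelation of
real BOLD signals, or realistic connectome topology — synthetic edges
are exchangeable apart from the planted component.

## Problem sizes and numerical choices

The packaged benchmarks use reduced resampling depths chosen to keep
the suites fast while preserving the qualitative behaviour of the full
defaults: consensus recovery runs 50 outer repeats × 100 inner
bootstraps (the full pipeline defaults are 1000 × 1000), and NBS
calibration uses 200 null datasets of 60 subjects × 30 nodes with 200
permutations. Planted-subgroup recovery at d = 3 is insensitive to this
reduction (ARI = 1.0 either way); recovery at weak effects would
benefit from the full depths.

Other numerical conventions: p-values use the add-one estimator
everywhere (no zero p-values); consensus proportions for never-sampled
pairs are 0 with a warning; thresholds compare with exact ≥; node ids
are 0-based internally; all generators and permutation streams are
`numpy` `Generator`-based and fully determined by their seeds.

## Interfaces

Stages are importable functions first; the CLI (`connstrat simulate |
connectome | cluster | nbs | summarize | overlap | stats | run`) is a
thin wrapper for shell use. Tables are TSV with header, matrices
headerless TSV squares, reports JSON; every output directory carries a
`manifest.json` with settings, seeds and package version. The
config-driven `run` subcommand validates all stage options (naming the
offending field) before executing, and `--dry-run` validates without
computing.

## Known limitations

- No spatial preprocessing: inputs are already-parcellated time series
  or connectomes.
- No missing-data handling in clustering inputs (rejected at the door).
- Edgewise models are OLS only (no mixed effects, no heteroscedasticity
  correction); permutation inference absorbs mild misspecification.
- The rotation-cost criterion is a behavioural re-implementation, not a
  port; on borderline inputs it may rank candidate C differently from
  the R original.
- `cut_tree` label numbering follows merge order, so cluster ids are
  arbitrary (compare partitions with ARI, not label equality).
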