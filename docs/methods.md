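# Methods

This note documents the models, estimators, defaults, and evaluation
protocol implemented in `devtraj`, including the design choices made where
the underlying methods are conventionally under-specified.

## Data model and preprocessing

All stages operate on a gene × sample matrix with per-sample metadata
(species, brain region, age in postconception days, PCD).  Postnatal ages
are folded onto the same clock by adding the gestation length (266 d
human, 165 d macaque), so one monotone axis covers pre- and postnatal
development; ages are analysed on the log2 scale, which makes early
development — where expression changes fastest — approximately linear in
the regressors.

Preprocessing follows the field's convention for intensity-like data:
genes are kept when expressed (> 0) in at least 80% of samples
(`min_fraction`, config); values are log2(x + 1) transformed
(`pseudocount` config; the platforms this emulates deliver normalized
positive intensities, for which +1 is a no-op at realistic magnitudes);
z-scoring uses the population standard deviation (ddof = 0) so the
three-point example (1, 2, 3) → (−1.2247, 0, 1.2247) is exact — the
sample-sd convention is a flag.  Constant genes become zero rows and are
flagged rather than dropped.  When samples from different platforms or
species are combined, each dataset is standardized gene-wise first; no
surrogate-variable batch model is fitted.

An age-boundary split assigns a sample whose age equals the boundary to
the early side: the demarcation age labels the *last early* time point.

## Stage demarcation

Samples are clustered with agglomerative hierarchical clustering
(average and complete linkage) on distance 1 − Pearson correlation
between expression profiles, and the dendrogram is cut into two groups.
The labels are then projected onto the age axis: every cut between
adjacent distinct ages is scored by its label disagreement (replicates at
an age are inseparable, so replicate splits count as disagreements); the
minimum-disagreement cut wins, ties going to the earliest cut
(conservative: the earliest plausible transition).  The result is the
interval (last early age, first late age), a purity score
1 − disagreements/n, a reliability flag (purity ≥ 0.75 by default), and a
cross-linkage consistency flag.  Per-region results are reported
individually; no rule for combining regions into a species-level range is
imposed.

## DNB critical-transition scan

The composite index CI = SD_d · PCC_d / PCC_o is computed per sliding
window of `width` samples (default 4, step 1) over the age-sorted series,
on globally z-scored data — global standardization is essential, since a
per-window re-scaling would erase exactly the fluctuation rise the first
DNB criterion looks for.  Within-window SD uses ddof = 1.

The dominant-group search, which the DNB framework leaves open, is:
cluster genes within the window on 1 − |PCC| (average linkage, cut at
1 − `corr_cut`, default 0.75), tighten each flat cluster by iteratively
dropping the member with the lowest mean |PCC| to the rest until all
members reach `corr_cut` (average linkage chains weakly-correlated genes
when windows are short), keep clusters of ≥ `min_size` (default 5)
genes, and score each; the window's dominant group is the max-CI
candidate.  The peak window across the series gives the transition age;
a transition is *called* only when the peak CI exceeds twice the median
window CI (`peak_factor`, config) — otherwise the no-transition flag is
set.  A zero PCC_o is reported as +inf with a flag, never as NaN.

Reported DNB membership applies the fluctuation criterion: a peak-group
member is kept only when its peak-window SD is at least `sd_ratio`
(default 1.5) times its median window SD.  In short windows, genes can
align with a group's correlation pattern by chance; requiring elevated
deviation is precisely the first DNB criterion and removes such
hitchhikers.  The refinement never shrinks the group below `min_size`.

## Heterochrony

Screens: (i) age effect by polynomial regression on log2 age, degrees
1–3, degree chosen by adjusted r², F-test against the intercept-only
model; (ii) species divergence by ANCOVA — the full model adds a species
main effect and species × polynomial interactions, and the partial
F-test compares it with the shared-polynomial model.  Both screens use
P < 0.05 with no multiple-testing correction, a deliberate fidelity
choice to the conventional screening recipe; callers can correct
externally if desired.

Shift estimation: per-species polynomial fits (the screened degree) are
evaluated on a 50-point grid spanning the *overlapping* log2-age range of
the two species, z-scored, and aligned by dynamic time warping with
symmetric steps and both endpoints pinned (open ends would make the
displacement statistic unidentifiable).  The shift is the mean signed
displacement (human index − macaque index) along the warping path,
averaged over the interior of the path — cells more than 10% of the grid
away from both ends — because the pinned corners force the displacement
to zero there and bias the untrimmed mean toward zero.  The displacement
is converted to log2-age units via the overlap span.  Registration on a
common overlap grid (rather than mapping each species' own span to
[0, 1]) keeps a time shift of δ log2-age units equal to δ on the warping
grid; per-species normalization would confound range differences with
timing and can even flip the sign of a genuine shift.  A flat fitted
curve leaves the shift undefined (class none): a time shift of a
trajectory without curvature is indistinguishable from a vertical
offset, which the z-scoring removes.

Significance: parametric bootstrap under the null of a shared trajectory
— pooled polynomial fit, per-species residuals resampled with
replacement and rescaled by √(n/(n−p)) to undo the variance deflation of
fitted residuals, shift recomputed per simulated dataset (default 1000),
add-one-corrected two-sided p.  Classes: neoteny iff shift > 0 and
P < 0.05; acceleration iff shift < 0 and P < 0.05; none otherwise.

## Differential expression, markers, enrichment

Early-vs-late testing uses Welch's unequal-variance t-test per gene on
log2 values, Benjamini–Hochberg adjustment over all tested genes, and a
double gate: FDR < 0.05 *and* linear fold change > 1.5.  A count-model
package is deliberately not used — the intended inputs are continuous
log-scale intensities.  Degenerate zero-variance genes get p = 1 when the
means agree and p = 0 otherwise.

Cell-type markers: a gene marks the cell type in which its mean
expression is at least `fold` (default 5) times the maximum over all
other types; a gene expressed in exactly one type is a marker of that
type (the ratio is infinite), all-zero genes are not markers.

Enrichment is the one-sided (over-representation) Fisher exact test —
equivalently the hypergeometric upper tail — per gene set after
intersecting sets with the universe, BH-corrected across sets; odds
ratios use the Haldane half-count correction when a table cell is zero.
The default universe is the filtered expressed gene list (config).

## Co-expression networks

Module detection (on early-stage data): soft power chosen as the
smallest exponent in 1..20 whose connectivity distribution fits
scale-free topology with r² ≥ 0.8 (log-log regression over connectivity
bins, negative slope required; max-r² fallback with a warning);
unsigned adjacency |corr|^power; topological overlap
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij); average
linkage on 1 − TOM with a static height cut (default 0.95) and a minimum
module size of 30, everything else module 0.  The cut height default was
set from planted two-block recovery (blocks of 50 genes at within-block
correlation 0.7 are recovered with ARI ≈ 1); a cut of 0.99 merges the
background into one cluster at realistic sample sizes.  Optional
covariate residualization (sex, region) runs per gene before network
construction when covariates are supplied.

MDC: connectivity of a pair is |corr|^power within a stage;
MDC = log2(mean early connectivity / mean late connectivity), so the
sign convention is coherent (a raw ratio is positive for both gain and
loss).  Classes gain/loss require both |MDC| > τ (default 0.1) *and*
that the whole 95% stage-wise bootstrap confidence interval of the log
ratio clears ±τ; otherwise none.  The interval gate is necessary because
a factor-driven module's pairwise correlations all reflect one latent
sample path: the connectivity log-ratio has sampling noise of order 1 at
tens of samples per stage, so a fixed threshold alone cannot distinguish
"no change" from noise.  MDC antisymmetry (swapping stages negates the
value) is exact.

Within-module networks: pairwise mutual information via the rank-based
Gaussian-copula closed form MI = −0.5·log(1 − ρ*²) with
ρ* = 2 sin(π ρ_s/6) from the Spearman correlation — chosen because the
sample sizes here (tens) are far too small for histogram estimators; a
permutation null (independently permuted rank vectors) sets the edge
threshold at the 1 − α/n_pairs quantile (α = 0.05, 20 000 permutations).
The data processing inequality then removes, in every triangle, the
weakest edge when it is weaker than both others by the factor
1 − `dpi_tolerance` (default 0.15).  Key drivers are genes whose ≤ N-hop
neighborhood (default 2) exceeds the mean by one standard deviation;
early-specific hubs are early-network hubs absent from the late-network
hub list.

## Synthetic data generator

The generator emulates, on the log2 scale with Gaussian noise
(σ = 0.3), the structures the analyses target, and exponentiates so the
emitted matrices are linear-scale and flow through the same
preprocessing as real data.  Default age grids follow the human and
macaque study sampling (8–25 PCW prenatal ages plus a thinned postnatal
series; transitions at 175 PCD human, 119 PCD macaque), with 2
replicates per age by default.

Gene roles (disjoint; 300 genes by default):

- **Ordinary genes** (65): cubic polynomial trajectories in normalized
  log2 age, shared between species.
- **Stage-switch genes** (100): flat baseline plus a mean step of
  ±`switch_delta` (default 1.0) after the species' transition age, half
  up half down.  Flat baselines make the planted offset the entire
  within-stage effect — these genes emulate stage markers, and they are
  what the demarcation and DE analyses should find.
- **DNB genes** (20): flat baseline; inside a ±1-age-step window around
  the transition their noise is drawn from an equicorrelated Gaussian
  (pairwise correlation 0.9) with the sd inflated 3×; independent noise
  elsewhere.  The equicorrelated single-parameter structure is the
  simplest that satisfies all three DNB criteria at once.
- **Heterochronic genes** (15 neoteny + 10 acceleration): rise-and-fall
  (parabolic) trajectories with guaranteed curvature and the vertex
  inside the sampled range; the human trajectory is evaluated at
  log2 age − δ with δ = ±1.0.  Curvature is required for
  identifiability — shifting a near-linear trajectory only shifts its
  level — and emulates the strongly age-related genes that survive the
  screens in real data.
- **Module blocks** (3 × 30): flat baseline plus latent-factor noise
  whose loading differs by stage; classes cycle gain (0.7 early / 0.2
  late), loss (reversed), none (0.45 / 0.45).  The first gene of each
  block is an observed regulator: it emits the factor itself during the
  early stage and decouples afterwards — a planted early-specific hub.
- **Cell-type markers** (5 types × 8 genes, in the cell-type mean table
  only): the marker's own-type mean is `marker_fold` (default 5) times
  the maximum over other types.

`null_dataset` zeroes every planted effect *and* the baseline
trajectories: a smooth age trend is itself a genuine early/late mean
difference, so a calibration null must not contain one.  Generation is
bit-deterministic per seed.

What the generator does **not** emulate: probe-level microarray
artifacts, RNA-seq count noise, single-cell dropout, region-specific
structure, or cross-platform batch effects.  Passing the planted-truth
studies therefore demonstrates correctness of the estimators under the
stated generative model, not performance on any particular real dataset.

## Evaluation protocol (what `scripts/acceptance.py` computes)

All studies derive per-replicate seeds from one base seed.

1. **Demarcation**: 100 datasets with the stage step reduced to 0.6
   (offset/noise = 2); fraction whose recovered interval brackets the
   planted transition age.
2. **DNB**: 100 datasets at 20 replicates/age (the sample density at
   which the windowed covariance is specified); fraction with the CI
   peak inside the planted fluctuation region, and (first 50) fraction
   with membership Jaccard ≥ 0.6.
3. **Composite-index oracle**: max |difference| vs a naive double-loop
   implementation on 100 random 10×8 matrices.
4. **Heterochrony**: 200 planted genes — sign recovery and median
   |shift error|; 500 null genes × 1000 bootstrap simulations — false
   positive rate at P < 0.05.
5. **DE**: 50 null datasets — fraction of genes at FDR < 0.05; 50
   planted datasets — switch-gene recall.
6. **Fisher oracle**: exhaustive tables for universes ≤ 30 plus 2000
   random tables with universes ≤ 200, against exact rational tail sums.
7. **TOM oracle / modules / MDC**: brute-force TOM agreement; two-block
   ARI; class recovery over 50 datasets at 3 replicates/age (≥ 20
   samples per stage, the density at which the block correlations are
   specified to be measurable) and exact antisymmetry.
8. **Key drivers**: star-graph exactness; planted-regulator top-5% rank
   and early-specific-hub recovery over 50 datasets.
9. **Determinism**: two full pipeline runs with one seed compared
   byte-for-byte.

## Known limitations

- The DNB dominant-group search and peak-significance rule are
  heuristics (the framework specifies only the index); all parameters
  are config-exposed.
- DTW shifts are mildly biased toward zero when the shift is an
  appreciable fraction of the overlapping range, even with interior
  trimming; the bootstrap p-value is unaffected since the null uses the
  same estimator.
- The static TOM tree cut is a simplification of dynamic tree cutting;
  fine module substructure at similar heights will not be separated.
- MDC "none" calls are interval-based non-rejections, not equivalence
  proofs.
- The screens' uncorrected P < 0.05 thresholds inflate the screened-gene
  count under complete nulls by design; downstream shift significance is
  separately calibrated.
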