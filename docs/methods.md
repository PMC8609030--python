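# Methods

This note documents the statistical model behind `coexdyn`, the choices
made where the design was genuinely open, and what the synthetic-cohort
tests do and do not demonstrate.

## Cohort structure and windowing

The package targets prospective designs: each subject is sampled
repeatedly, and each sample carries an offset in days to the subject's
(pseudo-)diagnosis.  Analysis windows are placed every `step_days`
(default 10) from `span_days` (default 600) before diagnosis to day 0.
For a window at `w` days before diagnosis, each subject contributes the
single sample minimizing `|days_before − w|`, included only when that gap
is below `max_offset_days` (default 100); ties go to the earlier-drawn
sample, which makes assignment a deterministic function of the sample
table.  Consequence worth noting: with sparse sampling (e.g. 90-day
visits) adjacent windows largely reuse the same samples, so window-level
statistics are strongly autocorrelated in time; the windows resolve time
only down to the sampling cadence, not to `step_days`.

Sample QC removes samples whose mean Pearson correlation with all other
samples is below 0.95, in a single pass.  This criterion presumes the
normalized-array regime where the between-gene mean profile dominates
residual variation; it is meaningless for data standardized per gene.

Per window, each case sample is matched to a same-sex control sample with
minimal |age difference|, greedily in a seeded random case order, without
reuse inside a set.  If no candidate lies within `age_tolerance_days`
(default 90 — the matching literature offers no canonical value; 90 days
is tight relative to the cohort's age spread while keeping matches
findable at edge windows), the nearest same-sex control is accepted and
the warning recorded in the run manifest.  Two control sets are drawn
independently; sets may overlap when the control pool is small.  Every
downstream statistic is computed once per control set and the statistics
averaged — pooling the sets instead would double the control sample size
and bias any statistic whose noise floor depends on n (see below).

## Network construction

Unsigned adjacency `a_ij = |r_ij|^β` with β = 12 for network construction
and β = 8 for connectivity statistics; both configurable.  Unsigned is the
coherent choice for even-powered |correlation| statistics, where positive
and negative correlation are deliberately equivalent.  The topological
overlap `t_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)` uses the standard
convention in which the shared-neighbour sum excludes `u ∈ {i, j}`; with
the zero-diagonal adjacency this is exactly `(A·A)_ij`, and a literal
all-nodes variant with `a_ii = 1` is available behind `include_self`.
Constant genes get zero correlation (logged), never NaN.

Module detection is deliberately simpler than the full dynamic hybrid
tree cut: average-linkage clustering of `1 − TOM`, a fixed-height cut,
eigengene merging, then a minimum-size filter.  Numerical rationale for
the default cut height of 0.9998: at β = 12 a module with within-module
correlation r has TOM ≈ r¹² (for a uniform module the TOM entry collapses
exactly to the adjacency), so dissimilarity sits at 1 − r¹² ≈ 1 − 10⁻³…10⁻²
for r ≥ 0.55, while uncorrelated genes at n ≥ 40 samples sit at
1 − O(10⁻⁶).  A cut must fall between those scales; 0.9998 does so with
margin on both sides.  Merging runs *before* the size filter (clusters of
≥ 3 genes participate), so sub-branches of one true module reunite via
their near-identical eigengenes instead of being discarded as undersized.
Modules are colour-labelled in size order with ties broken by smallest
member ID, which makes detection invariant to gene input order.

The reference partition is built once from the case samples nearest 180
days before diagnosis and never recomputed: all time-course comparisons
measure how connectivity *within fixed gene sets* changes, not how module
boundaries move.

## Differential connectivity and permutation inference

`MC = Σ_{i<j} t_ij` over a module's genes, with TOM computed on the module
submatrix (the whole-network variant is orders of magnitude more
expensive and changes t_ij only through third-party neighbour terms that
cancel in practice at these powers; it remains available by passing the
full gene set).  `MDC = MC_cases / mean_s(MC_controls,s)`.

The permutation test shuffles case/control labels over the pooled window
samples preserving group sizes, and — critically — rebuilds pseudo-control
sets with the *observed sets' sizes and overlap pattern* (index positions
into the unique control union).  The noise floor of a TOM sum rises
steeply as group size falls (the 8th power amplifies correlation noise:
`E[r̂⁸]` for null data at n = 15 is orders of magnitude above r⁸), so a
permutation scheme that alters group sizes is not a null of the observed
statistic at all; in simulation the naive scheme produced ~80% false
"gain" calls.  With structure preserved, the null rejection rate at
α = 0.05 measures 0.02–0.08 across 500 synthetic null datasets.

`p_gain` is the fraction of permutations with MDC above the observed
value, `p_loss` below; they sum to ≤ 1 (ties excluded).  Benjamini–
Hochberg runs across a module's windows separately for each tail;
`adjusted_q` is the smaller of the two.  The multiplicity family
(windows within module) is a package choice — families across modules or
sexes are equally defensible and can be layered on the output table.
Windows with fewer than `min_samples_per_group` (default 10) samples in
any group are reported as missing, not zero.

Gene-level: `GC_i` is the within-module adjacency row sum at β = 8;
`δH_i = GC_cases − GC_controls` and `GDC_i = GC_cases/GC_controls` share
the MDC permutation scheme.  Ranking: descending δH within each sex
(rank 1 = largest), final rank = sum, ties broken by the larger per-sex
δH then gene ID — fully deterministic.

A caution that shapes the tests: because of the `E[r̂⁸]` bias, the
*expected observed* MDC under a planted correlation shift 0.3 → 0.6 at
n = 100/group is far below the population ratio (0.6/0.3)⁸ = 256
(typically 20–130, with several-fold seed-to-seed spread driven by the
realized variance of the shared module factor).  MDC magnitudes are
therefore comparable between groups of equal size at one window, but not
across sample sizes, and should be read as test statistics rather than
effect-size estimates.  The exactness of the computation itself is tested
on data constructed to realize the population correlation matrix exactly,
where MDC = 256 is reproduced to relative 1e-8.

## Module eigengenes and differential expression

The eigengene is the first principal component of the module's
gene-standardized expression over the *reference* samples; the loadings,
gene means and gene scales from the reference window define a fixed affine
map through which every other window is projected.  Re-centering per
window would re-zero each window's scores and destroy cross-time
comparability, which is the entire point of the projection.  Genes are
scaled to unit variance before the PCA (conventional for eigengenes;
disable with `scale=False`); the sign is fixed so the largest-magnitude
loading is positive.  Group comparisons use two-sided Welch t-tests (the
unequal-variance form is the safe default when connectivity — hence ME
variance — is exactly what differs between groups).  Degenerate inputs
(zero variance in both groups, equal means) return t = 0, p = 1.
Per-probe differential expression applies the Bonferroni rule
0.05/n_probes.

## Enrichment

One-sided hypergeometric over-representation per module × gene set, BH
across all tests of a call.  The universe defaults to every gene in the
partition including unassigned grey genes (configurable) — the universe
choice moves p-values and should be reported with results.  When several
probes map to one gene, the gene counts once.

## The synthetic generator

`generate_cohort` plants modules through a one-factor model: gene g in
sample i is `x = λ_g·f + μ_g + ε`, with a fresh standard-normal factor f
per subject-draw (windows are analyzed cross-sectionally, so within-window
correlation is what must be controlled; smooth per-subject trajectories
would add autocorrelation the analysis never exploits).  Within-module
correlation is `λ²/(λ² + σ²)`; `loading_for_correlation` inverts this.
Case samples inside a module's shift window get their loadings multiplied
(optionally per sex, optionally extra for designated hub genes), planting
connectivity changes with mean shifts ≤ 5% or none.  Gene baselines are
drawn uniform on 5–15 log₂ units with residual SD 0.4 — spread dominating
noise, as on normalized arrays, so replicate samples correlate above the
0.95 QC threshold.  Defaults mirror the emulated study: 60 cases vs 325
controls, 600-day span, ~90-day draw interval.  Subjects' draw times sit
on a jittered grid so every window is populated.

Not emulated: array-level artifacts, batch and seasonal effects, probe
redundancy, genotype structure, non-Gaussian expression, and any real
biological covariance beyond the planted factors.  Passing tests therefore
demonstrate the *statistical machinery* — calibration, power against
planted effects, exactness of the algebra — not robustness to real-data
pathology.

## Problem sizes used by the test-suite and acceptance script

Chosen as the smallest sizes at which each check has adequate statistical
power: null calibration at 500 datasets (8 genes, 15/group, M = 200);
planted-gain detection at 50 genes, ~105 samples/group, M = 1000, 20
seeds; time-course localization on densely sampled cohorts (10-day draws,
30 subjects/group, M = 200) so windows resolve the planted 230–180-day
shift; hub recovery at base correlation 0.4 with ~154 samples/group
(at r = 0.3, n = 100 the top-5 recovery is genuinely underpowered);
module recovery from 100 reference samples.  The demo keeps 200 genes,
80 subjects and M = 200 to finish in well under five minutes on one CPU.

## Known limitations

- The fixed-height tree cut assumes modules separate cleanly from noise in
  TOM scale; heavily overlapping or weak modules (r < ~0.5 at β = 12 with
  n ≲ 50 samples) fragment or vanish where the hybrid dynamic cut might
  recover them.
- MDC magnitudes are biased by finite-sample correlation noise (see
  above); only within-design comparisons and permutation p-values are
  interpretable.
- Greedy control matching is order-dependent (seeded); an assignment-
  problem matcher would minimize total age distance globally.
- BH across windows treats windows as the family even though adjacent
  windows share samples under sparse designs; the q-values are then
  conservative in the dense regime and approximately valid, not exact,
  under sharing.
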