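# Methods

This note documents the models, conventions and numerical choices behind
`ginscore`, in the spirit of a statistical-software methods appendix. It
states no empirical claim that the test suite or `scripts/acceptance.py`
does not itself compute.

## Fraction of genome altered

A copy-number profile is a set of non-overlapping segments per chromosome,
0-based half-open internally. FGA is the length-weighted fraction of
segments whose log2 ratio magnitude *strictly* exceeds a threshold
(default 0.2):

    FGA = Σ{ℓᵢ : |rᵢ| > τ} / Σ ℓᵢ .

Design choices:

* **Magnitude, not sign.** Deletions are alterations; the threshold is
  applied to |r|. A `linear` flag applies the same threshold to |v − 1| for
  profiles reported as linear ratios.
* **SEG dialect.** On-disk coordinates are 1-based inclusive
  (length = end − start + 1) and converted on read. File rows must have
  start < end, so 1-bp segments are not representable in the dialect —
  irrelevant at array/sequencing segment scales.
* **No ploidy or sex-chromosome correction**: the formula is applied
  uniformly to whatever segments are supplied.
* Rows with a non-finite segment value are dropped on read with a logged
  count (segmentation output occasionally contains missing means; imputing
  them would invent genome).

Invariants verified by property tests: FGA ∈ [0, 1]; non-increasing in τ;
invariant to coordinate rescaling and to splitting a segment into abutting
halves with the same ratio.

## Signature derivation

Per cohort, each gene's expression is Pearson-correlated with FGA across
the samples shared by the expression matrix and the FGA table (intersection
by sample id, dropped count logged; ≥ 3 shared samples required; zero-
variance genes excluded with a logged count). The signature at threshold t
is the intersection of the two per-cohort filters {r ≥ t}. Choices:

* **Positive correlations only** by default (r ≥ t, not |r| ≥ t): the
  published signature consists entirely of positively correlated genes and
  the enrichment score of a positively-coupled set is the intended readout.
  `absolute=True` exposes the two-sided alternative.
* **Effect size only**: no correlation p-value screening or multiplicity
  correction — selection mirrors the threshold-sweep design (grid
  0.2/0.3/0.35/0.4, target size 10–50 genes, warning outside the window).
* Gene matching is exact, case-sensitive symbol comparison. Scoring
  requires ≥ 50% of a set's genes to be present; missing genes are listed.
  The floor prevents silently scoring a handful of a 20-gene set.

## Single-sample enrichment (GIN) score

The classic integrated-ECDF single-sample statistic: per sample, ascending
tie-averaged ranks; walk genes by decreasing rank (ties broken by gene id
for determinism); in-set steps weighted rank^α normalized over the present
set genes (α = 0.25 default), out-of-set steps uniform; ES = sum of the
running ECDF difference over all positions. This is the summed-difference
variant, not the max-deviation GSEA statistic.

* Scores are **reported raw** by default. The published use of this score
  family reports values on an arbitrary, implementation-dependent scale
  (e.g. cutoffs in the tens); that scale is not reconstructable from the
  statistic's definition, and the downstream cutpoint search is
  scale-adaptive, so raw ES plus an explicit `normalize` flag (divide by
  the max − min range across the scored table) is the honest contract.
* Unnormalized scores are per-sample quantities: adding or removing other
  samples cannot change a sample's ES. The test suite checks this, the
  invariance to monotone per-sample transforms, and exact agreement
  (1e−12) with an independently coded brute-force walk for every gene
  universe of ≤ 8 genes and every proper subset.

## Comparison statistics

All tests are two-sided. scipy implements Pearson (t-transform p),
Mann–Whitney (exact when the pooled sample is tie-free and ≤ 12, else
normal approximation with tie and continuity corrections) and
Kruskal–Wallis (tie-corrected H, chi-square p; the all-values-identical
degenerate case is reported as H = 0, p = 1). The paired two-group test is
the Wilcoxon signed-rank test with Wilcoxon's zero-drop rule; for ≤ 15
non-zero pairs the two-sided p is computed by exact enumeration of the 2ⁿ
sign patterns on tie-averaged ranks (valid under ties), otherwise the
continuity-corrected normal approximation. Friedman's test is computed
here (within-subject tie-averaged ranks, chi-square statistic with k − 1
df divided by the tie-correction factor 1 − ΣΣ(t³ − t)/(nk(k² − 1)))
because scipy's version lacks tie correction. Exact/asymptotic switchover
thresholds are keyword-configurable.

Calibration: the acceptance suite drives each test with 2000 seeded null
replicates and requires a rejection rate in [0.03, 0.07] at α = 0.05.

## Survival analysis

lifelines provides the Kaplan–Meier estimator, the log-rank test and the
Cox model. Cox fits use Efron tie handling and Wald confidence intervals
and p-values; the Newton solver tolerance is tightened (`precision`
1e−12) so fits agree with R's `survival::coxph` to ~1e−9 on the frozen
20-patient reference fixture in the tests. Proportionality is checked with
lifelines' scaled-Schoenfeld residual test (rank time transform), one
result per fitted covariate.

### Maximally selected cutpoint

The cutpoint search uses the linear-rank formulation: each subject gets a
Nelson–Aalen log-rank score aᵢ = δᵢ − Ĥ(tᵢ); for a split putting the k
lowest marker values in one group, the statistic is

    z(k) = ( Σ_{low} aᵢ − k·ā ) / sqrt( k(n−k)/(n(n−1)) · Σ(aᵢ − ā)² ),

the standardized log-rank statistic under the permutation distribution of
group labels. Candidate cutpoints are midpoints between consecutive
distinct marker values whose two groups each contain ≥ `minprop` (default
0.1) of the samples; the cutoff is the argmax of |z| with ties resolved
toward the lower cutpoint. The p-value of the maximum is computed by
seeded permutation of the score-to-subject assignment (default 1000
permutations, p = (1 + #{max_perm ≥ max_obs}) / (1 + n_perm)) rather than
an asymptotic improved-Bonferroni bound: simpler, assumption-free, and
exactly calibrated by construction. Dichotomization into the "high" group
is strict (score > cutoff).

The tests verify the argmax and statistic against an exhaustive, loop-coded
scan on instances of up to 50 samples, permutation-p calibration under the
null (500 replicates, rejection in [0.03, 0.07]), and Wald CI coverage
≥ 93% in a two-group design with true HR 3.5, n = 86 and ~30% events.

## Synthetic cohorts

The generator produces the minimal structure each stage is designed to
detect; a fixed seed reproduces a cohort bit-for-bit (single
`numpy.random.default_rng` PCG64 stream per cohort).

* **Copy number.** Target FGA ~ Beta(2, 3) per sample (mean 0.4 — the
  instability scale of head-and-neck tumors; configurable, and
  `fixed_fga` overrides the draw). A 22-chromosome, 3-Gb toy genome is cut
  into 50–200 Dirichlet-partitioned segments; segments are flagged altered
  by a largest-first greedy subset-sum over a shuffled order until the
  altered length reaches the target, which lands the realized fraction
  within one segment of the target (checked at ≤ 0.02). Altered segments
  get |log2| ∈ (0.25, 1.2) with random sign; background segments
  |log2| ≤ 0.18. The recorded per-sample FGA is the realized ratio, which
  `compute_fga` reproduces exactly.
* **Expression.** Planted genes follow β·FGA + N(0, noise_sd) with the
  slope calibrated against unit noise, β = (r/√(1−r²))/sd(FGA), so the
  population gene-FGA correlation equals `target_r` (default 0.5) at the
  default noise_sd = 1 and tends to 1 as noise vanishes. Background genes
  are independent Gaussians with gene-specific intercepts. The planted
  subset is a deterministic evenly-spaced slice of the gene list, so two
  cohorts simulated over the same gene universe plant the same genes — a
  dual-cohort derivation needs a shared ground truth (an explicit
  `planted_genes` tuple overrides it). No co-expression, batch or count
  noise is modeled: recovery results on these cohorts demonstrate the
  selection logic, not robustness to real microarray/RNA-seq noise.
* **Survival.** Exponential event times with hazard
  h₀·exp(log_hr_per_sd · z-score), independent uniform censoring on
  (0, censor_horizon = 84 months, a 7-year follow-up window), and
  randomized 3-arm treatment and binary histology covariates mimicking a
  chemoprevention-trial design. Defaults: h₀ = 0.01/month, log HR 0.7 per
  SD.

Problem sizes used in the checked examples — derivation pair n = 200/30
with 1000 genes and 25 planted, held-out validation at n = 200, survival
designs at n = 86 with ~30% events, calibration suites at 200–2000
replicates — were chosen as the smallest sizes at which the targeted
properties (sensitivity ≥ 0.8, FDP ≤ 0.1, r ≥ 0.5, CI coverage ≥ 93%,
type-I error within ±0.02 of nominal) are statistically stable.

## Known limitations

* FGA from real arrays requires upstream normalization/segmentation, which
  is out of scope; the package consumes segmented profiles.
* The enrichment score's absolute scale is implementation-dependent;
  compare scores only within one scored table, or use the cutpoint search
  which is scale-free.
* The maxstat p-value is a permutation estimate: it has Monte-Carlo
  granularity 1/(n_perm + 1) and is itself subject to seed variation.
* The Cox model assumes proportional hazards; `ph_assumption_check` tests
  but does not correct violations (no time-varying coefficients).
* Synthetic cohorts are deliberately idealized (linear coupling, Gaussian
  noise, independent censoring); passing recovery tests does not certify
  performance on real cohorts with correlated genes, batch effects or
  informative censoring.
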