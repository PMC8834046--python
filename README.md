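# ginscore

A transcriptomic surrogate of genomic instability for squamous-cell
carcinogenesis studies.

Copy-number instability is a hallmark of tumors and of the premalignant
lesions (e.g. oral leukoplakia) that can progress to cancer, but measuring
it directly requires copy-number profiling. `ginscore` implements the
alternative: learn a small gene signature whose expression tracks the
**fraction of genome altered (FGA)** in cohorts where both expression and
copy number are available, then score any expression-only cohort with a
single-sample enrichment statistic — the **GIN score** — and relate that
score to histology groups and time-to-cancer outcomes. It is aimed at
researchers analyzing bulk expression cohorts of head-and-neck / oral
samples, and anyone who needs a tested, scriptable implementation of this
class of signature pipeline.

## What it computes

**FGA.** For a sample with copy-number segments of length ℓᵢ and log2 ratio
rᵢ,

```
FGA = Σ_{|rᵢ| > 0.2} ℓᵢ / Σ ℓᵢ
```

(strict threshold, deletions count via the absolute value; a linear-ratio
dialect thresholds |value − 1| instead).

**Signature derivation.** Every gene is Pearson-correlated with FGA in two
cohorts; the signature is the set of genes with r ≥ t in *both* cohorts,
with t swept over {0.2, 0.3, 0.35, 0.4} and t = 0.35 the default. The
package ships the published 20-gene signature (`data/gin20.gmt`) together
with its printed per-cohort correlations as a worked-example fixture.

**GIN score (ssGSEA).** Within each sample, genes are rank-normalized
(ascending, ties averaged) and walked in decreasing rank order. With N genes,
m of them in set S and weight exponent α = 0.25,

```
ES = Σ_j [ P_in(j) − P_out(j) ],
P_in(j)  = Σ_{i ≤ j, i ∈ S} rank_i^α / Σ_{i ∈ S} rank_i^α,
P_out(j) = Σ_{i ≤ j, i ∉ S} 1 / (N − m)
```

— the integrated difference of the in-set and out-of-set empirical CDFs.
The score depends only on each sample's own ranks, so it is invariant to
any monotone per-sample normalization.

**Association.** Pearson/Mann–Whitney/Kruskal–Wallis/signed-rank/Friedman
comparisons; Kaplan–Meier curves, log-rank tests, Cox proportional-hazards
models (Efron ties, Wald CIs) with a scaled-Schoenfeld proportionality
check; and a **maximally selected rank statistic** that dichotomizes the
score at the cutpoint with the largest standardized log-rank statistic,
with a seeded permutation p-value.

A synthetic-cohort module generates segmented copy-number profiles with
known FGA, expression matrices with a planted FGA-coupled gene subset, and
survival with a score-dependent hazard, so the whole pipeline is testable
without any data downloads.

## Worked example

Simulate two derivation cohorts (n = 200 and n = 30, 1000 genes, 25 planted
genes at population r = 0.5 with FGA) and one validation cohort (n = 86)
whose hazard increases with the planted-set score, then run the full
pipeline:

```python
from ginscore.simulate import SimulationConfig, simulate_cohort
shared = dict(n_genes=1000, n_planted=25, target_r=0.5)
simulate_cohort(SimulationConfig(n_samples=200, seed=1, **shared), out_dir="cohortA")
simulate_cohort(SimulationConfig(n_samples=30, seed=2, **shared), out_dir="cohortB")
simulate_cohort(SimulationConfig(n_samples=86, seed=3, log_hr_per_sd=1.0, **shared),
                out_dir="valid")
```

```sh
ginscore run --config run.yaml   # paths above + covariates: [arm, histology], seed: 7
```

The run report (`out/report.json`) from this exact configuration:

* signature: 21 genes at r ≥ 0.35 (threshold sweep 0.2 → 22, 0.3 → 22,
  0.35 → 21, 0.4 → 16) — the planted structure is recovered;
* validation: Pearson r(GIN score, true FGA) = 0.91 (n = 86,
  p = 2.6e-34) — the score is a faithful FGA surrogate in a held-out cohort;
* survival: maxstat cutoff 238.94 (standardized log-rank z = −4.16,
  permutation p = 0.002); 51 high- vs 35 low-score samples, log-rank
  p = 4.2e-05; multivariate Cox (score group + treatment arm + histology)
  HR = 5.20, 95% CI (2.15, 12.56), p = 0.00025 — high-score samples
  progress faster, as simulated.

The same stages are available piecewise (`ginscore simulate / fga / derive /
score / compare / survive`) and as library calls (`SignatureSelector`,
`SsgseaScorer`, `MaxstatCutpoint`, plus the functional API in each module).

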