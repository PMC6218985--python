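# Methods

## The model

The pipeline asks, per candidate driver gene and tumor type, whether the
gene's binary mutation status is associated with *genome-wide* disruption
of a molecular layer, and then aggregates the evidence across tumor types.

**Site-level tests.** Methylation beta values are bounded in [0, 1],
typically bimodal near 0 and 1, and the mutated/wild-type groups are
extremely unbalanced (mutation frequencies of roughly 5–40%), so the
per-CpG comparison uses the Wilcoxon rank-sum test. Two one-sided tests,
each at level α₁ = 0.01, define disjoint hyper- and hypo-methylated site
sets S⁺ᵢₖ and S⁻ᵢₖ; the genome-wide count nᵐᵢₖ = |S⁺| + |S⁻| is the test
statistic. No site-level multiplicity adjustment is applied, deliberately:
single sites are never reported, only the count. The expression arm uses
Welch two-sample t-tests at α₂ = 0.05 split by the sign of the mean
difference, excluding the driver from its own target count.

**Empirical null.** Counts are calibrated against passenger genes: within
each cohort, genes mutated in ≥ 5 samples with the relevant data, excluding
the candidate list, capped at the 500 most frequently mutated (ties at the
cutoff broken lexicographically so selection is order-independent). Every
(passenger, cohort) pair contributes its count to the pool; pairs are kept
without deduplicating genes across cohorts. The per-cancer p-value is the
inclusive exceedance fraction pᵢₖ = (1/|pool|) Σⱼ I(nᵐᵢₖ ≤ nᵐⱼ). A gene is
classified genome-wide hyper-methylated in cohort *k* if pᵢₖ < 0.05 and
|S⁺| > |S⁻|, hypo-methylated if pᵢₖ < 0.05 and |S⁺| ≤ |S⁻| (the tie goes to
hypo), and unclassified otherwise.

Passenger mutations are preferred over random sample splits as the null
because passenger status can itself correlate weakly with genome-wide
state; the `random_split_null` (36 percentages from 5–40% × 10 repetitions
= 360 counts per cohort) is provided as the sensitivity check. Notably the
synthetic generator reproduces this phenomenon: when strong planted drivers
exist, passenger counts are inflated above the random-split level through
finite-sample correlation between mutation indicator vectors, and the
passenger pool absorbs exactly that excess.

**Pan-cancer aggregation.** For gene *i* with eligible cohort set Aᵢ
(≥ 5 mutated samples with data), the observed total Σₖ∈Aᵢ nᵐᵢₖ is compared
with B resampled sums of |Aᵢ| uniform draws (with replacement) from the
pool; pᵢ is the fraction of resampled sums at least as large. B defaults to
10⁶; resampled sums are drawn once per |Aᵢ| stratum and shared by all genes
in it, which is statistically identical under the null and far cheaper. An
empirical p of exactly 0 is reported with a "< 1/B" annotation rather than
as evidence of p = 0. Benjamini–Hochberg is applied within strata of equal
|Aᵢ| because the observed totals (and their null distributions) scale with
the number of cohorts summed; drivers are genes with adjusted pᵢ < 0.05.
The reported direction is the per-cohort consensus ("both" when significant
cohorts disagree; none when no single cohort is individually significant,
which can legitimately coexist with a significant pan-cancer p).

**Downstream characterization.** For drivers significant in both arms, the
target-gene promoter direction is a majority vote over the gene's CpG sites
within 1,500 bp upstream of the TSS (ties and empty promoters uncalled).
Each of the four joint signatures — promoter-hyper/up (++), hyper/down
(+−), hypo/up (−+), hypo/down (−−) — is tested per cohort with a
hypergeometric upper tail (universe = genes with both a promoter call and
an expression call) and combined across cohorts with Fisher's method
(−2 Σ ln p ~ χ² with 2m df; exact zeros floored at 1e−300 with a warning).
Cross-cohort consistency is the median, over cohort pairs, of the
hypergeometric overlap p between the per-cohort differential sets.
Chromatin-regulator enrichment restricts the regulator lists to the
measured universe before testing.

## Numerical choices

* Wilcoxon: exact enumeration when both groups have ≤ 25 observations and
  no ties; otherwise the normal approximation with mid-rank tie correction
  and 0.5 continuity correction. The genome-wide counting path vectorizes
  the approximation across all sites and genes simultaneously (ranks are
  shared across genes, reducing the computation to two matrix products);
  cohorts of ≤ 50 samples fall back to per-site scalar tests.
* Missing beta values are dropped per site (the 5% QC cap keeps this safe);
  sites with an empty group are skipped and counted in a report. The QC
  missingness rule is strict: a site is removed only when its missing
  fraction exceeds 5%, computed over all methylation samples.
* Expression values are log1p-transformed before the Welch test by default.
  Expression is strongly right-skewed, and with mutated groups of ~10
  samples a raw-scale t-test is directionally biased (the small group's
  mean sits below the population mean more often than not), which inflates
  spurious "down" calls; the transform restores calibration and, being
  monotone, leaves direction labels meaningful. Degenerate zero-variance
  comparisons give p = 1 when means agree and p = 0 otherwise.
* The exact pan-cancer p (`pan_cancer_p_exact`) convolves the pool's
  integer count distribution m-fold and refuses supports beyond 2×10⁷,
  advising the Monte-Carlo path.
* Empirical p-values use inclusive ≥ comparisons throughout, with no +1
  small-sample correction, matching the estimator's definition.

## The synthetic generator

`simulate_cohorts` emulates the statistical structure the analysis assumes,
not genomic detail. Per site, beta values follow a two-component beta
mixture (low mode Beta(1.5, 15), high mode Beta(15, 1.5)) with a per-site
high-mode weight drawn uniformly, giving the 450K-style enrichment near 0
and 1; mixture weights and per-gene expression baselines are shared across
cohorts so sites and genes keep their character. Mutations are Bernoulli
per (gene, cohort) with frequency uniform in 5–40%. Planted methylation
drivers shift mutated samples' beta values on the logit scale (clipped to
[0.001, 0.999] first, so values stay in range) at 5% of sites, default
magnitude 1.5 logits; planted expression drivers scale 5% of genes by
e^±1.0. With promoter–expression coupling on, a driver's affected sites are
the promoter CpGs of its target genes and the targets split into a
hyper-methylated/down-regulated half and a hypo/up half, planting both
coupled signatures. Missing beta values are placed completely at random
(default 1%). Each simulated gene owns a disjoint block of
n_sites // n_genes CpG sites as its promoter. A single seed drives
everything through per-cohort spawned substreams; identical configuration
and seed reproduce identical data.

What the generator does *not* emulate: genomic coordinates and CpG
linkage, copy number, tumor purity, batch structure, mutual exclusivity of
driver mutations, or realistic expression covariance. Passing the recovery
tests therefore shows the procedure is correctly implemented and calibrated
under its own assumptions, not that it would recover any particular
biology from real cohorts.

## Default study scales

Calibration and recovery experiments run at: 3 cohorts × 200 samples ×
20,000 CpG sites × 2,000 genes, 50 candidate drivers (5 planted methylation
drivers, 5 expression drivers, 40 passengers behaving as null candidates)
and 120 background passenger genes (null pool of 360 counts). The type-I
experiments use one effect-free cohort with 200 candidates and 350
passengers, mirroring the per-cohort pool size of a full-scale analysis.
The pattern experiments use 2 cohorts × 200 samples × 10,000 sites × 1,000
genes with coupling on. Tests run the pan-cancer resampling at B = 10⁵;
the production default stays at 10⁶.

## Known limitations

* Effect sizes of real drivers are unknown; the planted defaults are
  calibration choices, and recovery rates do not transfer to weaker
  effects.
* The per-site mixture makes a minority of sites bimodal *across samples*
  within a site; at such sites the sign of a small mutated group's mean
  shift is noisy, so a few percent of affected sites can show the opposite
  sign even when the planted effect is recovered genome-wide.
* The empirical p has resolution 1/|pool| per cohort and 1/B pan-cancer;
  small pools make the uniformity of null p-values correspondingly coarse.
* Whether site-level direction should come from two one-sided tests (as
  here) or one two-sided test split by sign is a convention; both are
  supported by the underlying functions and the choice is documented.
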