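# methdriver

Pan-cancer identification of mutated driver genes whose mutations are
associated with **genome-wide** DNA-methylation changes (methylation driver
genes, MDGs) or gene-expression changes (expression driver genes, EDGs),
with downstream characterization of how promoter methylation and expression
of their target genes move together.

The package is aimed at cancer epigenomics analysts who have, per tumor
type, gene-level somatic mutation calls, CpG-site methylation beta values
(450K-style) and gene expression for the same patients, plus an externally
derived candidate-driver list.

## The statistic

For candidate driver *i* in tumor type *k*, every CpG site is tested for a
shift between mutated and wild-type samples with a one-sided Wilcoxon
rank-sum test at level 0.01 in each direction, giving hyper- and
hypo-methylated site sets S⁺ᵢₖ and S⁻ᵢₖ. The test statistic is the
genome-wide count

    nᵐᵢₖ = |S⁺ᵢₖ ∪ S⁻ᵢₖ|

with no site-level multiplicity adjustment — individual sites are never
interpreted, only the degree of genome-wide disruption. Significance is
judged against an **empirical null pool**: the same count computed for
passenger genes (recurrently mutated genes not on the candidate list),

    pᵢₖ = (1/|pool|) Σⱼ I(nᵐᵢₖ ≤ nᵐⱼ).

Across tumor types, the observed total Σₖ∈Aᵢ nᵐᵢₖ (Aᵢ = cohorts with ≥ 5
mutated samples) is compared with B = 10⁶ resampled sums of |Aᵢ| draws from
the pool, and the resulting pᵢ values are Benjamini–Hochberg adjusted
*within strata of equal |Aᵢ|*; MDGs are the genes with adjusted pᵢ < 0.05.
The expression arm mirrors this with Welch t-tests (on log1p values) and
up-/down-regulated gene counts. Drivers significant in both arms are then
profiled for the four promoter-methylation × expression signatures of their
targets (++, +−, −+, −−) by per-cohort hypergeometric tests combined with
Fisher's method.

## Worked example

```python
from methdriver import SimConfig, simulate_cohorts, PanCancerDriverModel

# 3 tumor types x 200 samples, 20,000 CpG sites, 2,000 genes; 5 planted
# methylation drivers, 5 expression drivers, 40 passenger candidates
bundles, truth = simulate_cohorts(SimConfig(seed=11))
model = PanCancerDriverModel(bundles, truth.candidates)
mdg = model.fit("methylation", B=100_000, seed=3)
print(mdg.summary())
```

```
Pan-cancer MDG analysis
  cohorts: 3  candidates tested: 50  (dropped: 0)
  null pool size: 360  resamples B: 100000
  drivers called (adj p < 0.05): 5

 gene  n_A  n_T      T_plus T_minus  observed_sum       p    p_adj direction  is_driver
G0000    3    3 C01,C02,C03                  3507 0.00000 0.000000     hyper       True
G0001    3    3 C01,C02,C03                  3751 0.00000 0.000000     hyper       True
G0002    3    3 C01,C02,C03                  3904 0.00000 0.000000     hyper       True
G0003    3    3 C01,C02,C03                  3961 0.00000 0.000000     hyper       True
G0004    3    3 C01,C02,C03                  3831 0.00000 0.000000     hyper       True
G0016    3    1                 C02          1273 0.04092 0.341000      hypo      False
...
```

The five called genes are exactly the five planted methylation drivers
(`truth.planted_mdgs`), each with its planted direction: `n_A` is the
number of cohorts where the gene is mutated in ≥ 5 samples, `n_T` the
cohorts individually significant (per-cancer empirical p < 0.05),
`observed_sum` the total differential-site count over those cohorts, and
`p`/`p_adj` the pan-cancer resampling p-value before/after grouped BH. An
empirical p of exactly 0 means "below 1/B" and is annotated as such in the
written tables.

The same model object fits the expression arm
(`model.fit("expression", ...)`) and feeds the downstream stages
(`model.pattern_analysis(...)`, `model.enrichment_analysis(...)`).

A command-line interface mirrors the library:
`methdriver simulate | validate | qc | site-test | build-null | call-mdg |
call-edg | random-split | enrich | patterns` (see `methdriver --help`).

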