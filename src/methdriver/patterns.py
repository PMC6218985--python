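"""Downstream characterization of called drivers.

Given a driver gene whose mutations disturb both the methylome and the
transcriptome, this module asks *how* the two layers move together:

* which target genes are dysregulated in every significant cohort (common
  targets), and whether known chromatin regulators are over-represented
  among them (hypergeometric upper tail);
* each target gene's promoter methylation direction -- majority vote over
  its CpG sites within 1,500 bp upstream of the TSS, ties and empty
  promoters uncalled;
* the four joint methylation x expression patterns ("++", "+-", "-+",
  "--"), each tested per cohort for enrichment beyond what independent
  direction calls would give, and combined across cohorts with Fisher's
  method;
* cross-cohort consistency: for every cohort pair, whether the driver's
  differential gene sets overlap more than chance (median pairwise p).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from statistics import median

import numpy as np
from scipy import stats

from .site_stats import (
    _ASYMPTOTIC_MIN_SAMPLES,
    _ranksum_pvalues,
    _scalar_site_loop,
    _welch_pvalues,
)

__all__ = [
    "RegulatorLists",
    "PatternResult",
    "identify_common_targets",
    "hypergeom_enrichment",
    "promoter_direction",
    "promoter_methylation_calls",
    "expression_direction_calls",
    "pattern_tests",
    "fisher_combine",
    "cross_cohort_consistency",
    "regulator_enrichment",
]

PATTERNS = (
    ("hypo", "down", "--"),
    ("hyper", "down", "+-"),
    ("hypo", "up", "-+"),
    ("hyper", "up", "++"),
)

_FISHER_FLOOR = 1e-300


@dataclass(frozen=True)
class RegulatorLists:
    """Chromatin-regulator gene lists used for enrichment tests.

    ``list_a`` is the broad catalogue of DNA/RNA/histone/chromatin-modifying
    enzymes (~720 genes); ``list_b`` the short list of master epigenetic
    regulators plus the DNA methyltransferases (21 genes by default). Both
    are restricted to the measured universe before testing.
    """

    list_a: frozenset
    list_b: frozenset

    def restrict(self, universe) -> "RegulatorLists":
        u = set(universe)
        return RegulatorLists(
            list_a=frozenset(self.list_a & u), list_b=frozenset(self.list_b & u)
        )


@dataclass
class PatternResult:
    """Joint methylation x expression pattern summary for one driver."""

    driver: str
    cohorts_used: list[str]
    dm_count: float  # mean |DM| across cohorts
    de_count: float  # mean |DE|
    dm_and_de_frac: float  # mean |DM & DE| / |DE|
    p_dmde: float  # Fisher-combined overlap p
    pattern_p: dict[str, float]  # "--", "+-", "-+", "++" -> combined p
    pattern_counts: dict[str, list[int]] = field(default_factory=dict)
    per_cohort_p: dict[str, list[float]] = field(default_factory=dict)
    p_methyl_median: float = float("nan")
    p_exp_median: float = float("nan")


def identify_common_targets(
    per_cohort_p: dict[str, dict[str, float]],
    cohorts,
    alpha: float = 0.05,
) -> set[str]:
    """Genes with p < alpha in *every* cohort of the driver's T_i.

    ``per_cohort_p`` maps cohort -> {gene: differential-expression p}. Genes
    missing a p-value in any cohort are excluded.
    """
    cohorts = list(cohorts)
    if not cohorts:
        raise ValueError("driver has no significant cohorts (empty T_i)")
    common = None
    for c in cohorts:
        hits = {g for g, p in per_cohort_p[c].items() if p < alpha}
        common = hits if common is None else common & hits
    return common


def hypergeom_enrichment(universe: int, list_size: int, selected: int, overlap: int) -> float:
    """Upper-tail P(X >= overlap) for X ~ Hypergeom(universe, list_size, selected)."""
    if not (0 <= list_size <= universe and 0 <= selected <= universe):
        raise ValueError("list_size and selected must be within the universe")
    if overlap > min(list_size, selected) or overlap < 0:
        raise ValueError("overlap inconsistent with list_size/selected")
    return float(stats.hypergeom.sf(overlap - 1, universe, list_size, selected))


def promoter_direction(site_calls) -> str:
    """Majority vote over a gene's promoter CpG direction calls.

    ``site_calls`` is an iterable of per-site labels (hyper/hypo/none).
    Ties and promoters with no called site are 'none'.
    """
    calls = list(site_calls)
    n_hyper = sum(1 for c in calls if c == "hyper")
    n_hypo = sum(1 for c in calls if c == "hypo")
    if n_hyper > n_hypo:
        return "hyper"
    if n_hypo > n_hyper:
        return "hypo"
    return "none"


def promoter_methylation_calls(
    bundle, driver: str, promoter_map: dict[str, list[str]], alpha_site: float = 0.01
) -> dict[str, str]:
    """Per-gene promoter methylation direction under a driver's mutation.

    Site-level one-sided Wilcoxon calls (at ``alpha_site``) are aggregated
    per gene by majority vote over its promoter sites. Genes whose promoter
    sites are all absent from the (QC-filtered) methylation matrix get no
    entry; the driver itself is excluded.
    """
    samples = bundle.methylation_samples
    values = bundle.methylation[samples].to_numpy(dtype=float)
    mut = bundle.mutation.loc[samples, [driver]].to_numpy(dtype=float)
    if len(samples) > _ASYMPTOTIC_MIN_SAMPLES:
        p_greater, p_less, tested = _ranksum_pvalues(values, mut)
    else:
        p_greater, p_less, tested = _scalar_site_loop(values, mut)
    p_greater, p_less, tested = p_greater[:, 0], p_less[:, 0], tested[:, 0]
    site_call = np.where(
        tested & (p_greater < alpha_site),
        "hyper",
        np.where(tested & (p_less < alpha_site), "hypo", "none"),
    )
    site_index = {s: i for i, s in enumerate(bundle.methylation.index)}
    out: dict[str, str] = {}
    for gene, sites in promoter_map.items():
        if gene == driver:
            continue
        rows = [site_index[s] for s in sites if s in site_index]
        if not rows:
            continue
        out[gene] = promoter_direction(site_call[rows])
    return out


def expression_direction_calls(
    bundle, driver: str, alpha_gene: float = 0.05, log_expression: bool = True
) -> tuple[dict[str, str], dict[str, float]]:
    """Per-gene expression direction (up/down/none) and raw p under a driver.

    The driver itself is excluded from its own target calls. Values are
    log1p-transformed before the Welch test unless ``log_expression`` is
    off (raw right-skewed expression biases small-group t-tests).
    """
    samples = bundle.expression_samples
    values = bundle.expression[samples].to_numpy(dtype=float)
    if log_expression:
        values = np.log1p(values)
    mut = bundle.mutation.loc[samples, [driver]].to_numpy(dtype=float)
    p, sign, tested = _welch_pvalues(values, mut)
    p, sign, tested = p[:, 0], sign[:, 0], tested[:, 0]
    calls, pvals = {}, {}
    for i, gene in enumerate(bundle.expression.index):
        if gene == driver:
            continue
        pvals[gene] = float(p[i])
        if tested[i] and p[i] < alpha_gene:
            calls[gene] = "up" if sign[i] > 0 else "down"
        else:
            calls[gene] = "none"
    return calls, pvals


def fisher_combine(p_values) -> float:
    """Fisher's method: X^2 = -2 sum(ln p) ~ chi-square with 2m df.

    Zeros are floored at 1e-300 with a warning (the log is undefined at 0).
    """
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        raise ValueError("cannot combine an empty p-value list")
    if (ps < 0).any() or (ps > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (ps == 0).any():
        warnings.warn("p-value of 0 floored at 1e-300 for Fisher combination")
        ps = np.maximum(ps, _FISHER_FLOOR)
    x2 = -2.0 * np.log(ps).sum()
    return float(stats.chi2.sf(x2, 2 * ps.size))


def pattern_tests(
    driver: str,
    cohorts,
    dm_calls: dict[str, dict[str, str]],
    de_calls: dict[str, dict[str, str]],
) -> PatternResult:
    """Per-cohort pattern enrichment, Fisher-combined across cohorts.

    ``dm_calls``/``de_calls`` map cohort -> {gene: direction}. The universe
    per cohort is the genes with both a promoter methylation call and an
    expression call. For each pattern (d_m, d_e), the per-cohort test is
    hypergeometric with N = universe, K = #genes methylated d_m, n = #genes
    expressed d_e, k = #genes with both.
    """
    cohorts = list(cohorts)
    if not cohorts:
        raise ValueError("no cohorts available for pattern analysis")
    per_cohort_p: dict[str, list[float]] = {lab: [] for *_, lab in PATTERNS}
    per_cohort_p["dmde"] = []
    pattern_counts: dict[str, list[int]] = {lab: [] for *_, lab in PATTERNS}
    dm_sizes, de_sizes, fracs = [], [], []

    for c in cohorts:
        dm = dm_calls[c]
        de = de_calls[c]
        universe = sorted(set(dm) & set(de))
        if not universe:
            raise ValueError(f"empty methylation/expression universe in cohort {c}")
        n_univ = len(universe)
        dm_set = {g for g in universe if dm[g] != "none"}
        de_set = {g for g in universe if de[g] != "none"}
        dm_sizes.append(len(dm_set))
        de_sizes.append(len(de_set))
        both = dm_set & de_set
        fracs.append(len(both) / len(de_set) if de_set else float("nan"))
        per_cohort_p["dmde"].append(
            hypergeom_enrichment(n_univ, len(dm_set), len(de_set), len(both))
        )
        for d_m, d_e, label in PATTERNS:
            k_set = {g for g in universe if dm[g] == d_m}
            n_set = {g for g in universe if de[g] == d_e}
            overlap = len(k_set & n_set)
            pattern_counts[label].append(overlap)
            per_cohort_p[label].append(
                hypergeom_enrichment(n_univ, len(k_set), len(n_set), overlap)
            )

    return PatternResult(
        driver=driver,
        cohorts_used=cohorts,
        dm_count=float(np.mean(dm_sizes)),
        de_count=float(np.mean(de_sizes)),
        dm_and_de_frac=(
            float(np.mean([f for f in fracs if not math.isnan(f)]))
            if any(not math.isnan(f) for f in fracs)
            else float("nan")
        ),
        p_dmde=fisher_combine(per_cohort_p["dmde"]),
        pattern_p={lab: fisher_combine(per_cohort_p[lab]) for *_, lab in PATTERNS},
        pattern_counts=pattern_counts,
        per_cohort_p=per_cohort_p,
    )


def cross_cohort_consistency(
    per_cohort_sets: dict[str, set],
    universe_per_pair,
) -> float:
    """Median pairwise overlap-enrichment p across cohort pairs.

    ``universe_per_pair`` is either a {(c1, c2): N} mapping (order-free) or a
    single integer N for all pairs. Returns NaN when fewer than two cohorts
    are available (single-cohort drivers have no pair to compare).
    """
    cohorts = sorted(per_cohort_sets)
    if len(cohorts) < 2:
        return float("nan")
    ps = []
    for i, c1 in enumerate(cohorts):
        for c2 in cohorts[i + 1 :]:
            if isinstance(universe_per_pair, int):
                n_univ = universe_per_pair
            else:
                n_univ = universe_per_pair.get(
                    (c1, c2), universe_per_pair.get((c2, c1))
                )
            s1, s2 = per_cohort_sets[c1], per_cohort_sets[c2]
            ps.append(
                hypergeom_enrichment(n_univ, len(s1), len(s2), len(s1 & s2))
            )
    return float(median(ps))


def regulator_enrichment(
    targets, regulators, universe
) -> tuple[int, float]:
    """Overlap count and hypergeometric p of a regulator list among targets.

    Both the target set and the regulator list are restricted to the
    measured ``universe`` before testing.
    """
    u = set(universe)
    t = set(targets) & u
    r = set(regulators) & u
    k = len(t & r)
    return k, hypergeom_enrichment(len(u), len(r), len(t), k)
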