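"""Two-group association statistics between mutation status and omics profiles.

The counting statistics defined here measure *genome-wide* disruption: for a
gene ``i`` mutated in a cohort, every CpG site (or every expression gene) is
tested for a shift between mutated and wild-type samples, and the numbers of
significant sites per direction -- |S+| hyper-methylated, |S-| hypo-methylated
(|G+| up-, |G-| down-regulated for expression) -- are the statistic. No
site-level multiplicity adjustment is applied: the counts themselves are later
compared against an empirical null pool, so individual site calls are never
interpreted.

Methylation uses the Wilcoxon rank-sum test (beta values are bounded, bimodal
and the two groups are extremely unbalanced); expression uses a Welch
two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DiffCount",
    "wilcoxon_site_test",
    "ttest_gene_expression",
    "diff_methylation_count",
    "diff_expression_count",
    "genome_wide_counts",
]

#: above this cohort size the vectorized normal approximation is used for
#: genome-wide counting; at or below it each site goes through the scalar
#: (possibly exact) test.
_ASYMPTOTIC_MIN_SAMPLES = 50

#: largest group size for which the scalar Wilcoxon uses exact enumeration.
_EXACT_MAX_GROUP = 25


@dataclass(frozen=True)
class DiffCount:
    """Differential counts for one (gene, cohort, modality).

    ``n_plus``/``n_minus`` are |S+|/|S-| for methylation or |G+|/|G-| for
    expression; ``n_m`` = |S+ u S-|. The two direction sets are disjoint by
    construction (two one-sided tests each at the same level), so
    ``n_m == n_plus + n_minus`` always holds.
    """

    gene: str
    cohort: str
    n_plus: int
    n_minus: int
    modality: str = "methylation"

    @property
    def n_m(self) -> int:
        return self.n_plus + self.n_minus


def wilcoxon_site_test(mutated, wildtype) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum p-values in both directions.

    Returns ``(p_greater, p_less)``: evidence that values in ``mutated`` are
    stochastically greater (resp. less) than in ``wildtype``. Missing values
    must already be removed. Exact enumeration is used when both groups have
    at most 25 observations and no ties straddle the groups; otherwise the
    normal approximation with mid-rank tie correction and continuity
    correction.
    """
    x = np.asarray(mutated, dtype=float)
    y = np.asarray(wildtype, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:  # every observation identical: no evidence
        return 1.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if max(x.size, y.size) <= _EXACT_MAX_GROUP and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    p_greater = stats.mannwhitneyu(x, y, alternative="greater", method=method).pvalue
    p_less = stats.mannwhitneyu(x, y, alternative="less", method=method).pvalue
    return float(p_greater), float(p_less)


def ttest_gene_expression(mutated, wildtype) -> tuple[float, int]:
    """Welch two-sample t-test: ``(p_two_sided, direction_sign)``.

    ``direction_sign`` is ``sign(mean(mutated) - mean(wildtype))``. Degenerate
    zero-variance inputs: equal means give ``(1.0, 0)``; unequal means with no
    within-group variance give ``(0.0, sign)``.
    """
    x = np.asarray(mutated, dtype=float)
    y = np.asarray(wildtype, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need at least 2 values")
    diff = x.mean() - y.mean()
    sign = int(np.sign(diff))
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        return (1.0, 0) if diff == 0 else (0.0, sign)
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.pvalue), sign


# ---------------------------------------------------------------------------
# vectorized genome-wide paths


def _tie_correction(values: np.ndarray) -> np.ndarray:
    """Per-row sum of t^3 - t over tied groups, ignoring NaN."""
    n_rows = values.shape[0]
    out = np.zeros(n_rows)
    sv = np.sort(values, axis=1)  # NaNs sort to the end
    tied_rows = np.nonzero((np.diff(sv, axis=1) == 0).any(axis=1))[0]
    for r in tied_rows:
        row = sv[r][~np.isnan(sv[r])]
        _, counts = np.unique(row, return_counts=True)
        t = counts[counts > 1].astype(float)
        out[r] = np.sum(t**3 - t)
    return out


def _ranksum_pvalues(
    values: np.ndarray, mut_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-sided rank-sum p-values for every (site, gene) pair at once.

    Parameters
    ----------
    values : (n_sites, n_samples) float array, NaN = missing.
    mut_mask : (n_samples, n_genes) 0/1 array of mutation indicators.

    Returns ``(p_greater, p_less, tested)``, each (n_sites, n_genes); a pair
    is tested only if both groups are non-empty after dropping missing values.

    Sites share their rank vector across genes, so the whole computation
    reduces to two matrix products; the normal approximation carries the
    mid-rank tie correction and a 0.5 continuity correction.
    """
    valid = ~np.isnan(values)
    ranks = stats.rankdata(values, axis=1, nan_policy="omit")
    ranks = np.where(valid, ranks, 0.0)

    mask = mut_mask.astype(float)
    n1 = valid.astype(float) @ mask  # mutated with data, per (site, gene)
    n_tot = valid.sum(axis=1, keepdims=True).astype(float)
    n2 = n_tot - n1
    r1 = ranks @ mask  # rank sum of the mutated group

    tested = (n1 > 0) & (n2 > 0)
    mu = n1 * (n_tot + 1) / 2.0
    ties = _tie_correction(values)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (
            n1
            * n2
            / 12.0
            * ((n_tot + 1) - ties / (n_tot * (n_tot - 1)))
        )
        sd = np.sqrt(var)
        z_greater = (r1 - mu - 0.5) / sd
        z_less = (r1 - mu + 0.5) / sd
    p_greater = stats.norm.sf(z_greater)
    p_less = stats.norm.cdf(z_less)
    degenerate = ~tested | ~np.isfinite(sd) | (sd == 0)
    p_greater = np.where(degenerate, 1.0, p_greater)
    p_less = np.where(degenerate, 1.0, p_less)
    return p_greater, p_less, tested


def _welch_pvalues(
    values: np.ndarray, mut_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Welch t-test p-values and mean-difference signs, vectorized.

    ``values`` is (n_features, n_samples) without missing entries; returns
    ``(p_two_sided, sign, tested)`` of shape (n_features, n_genes). Features
    require >= 2 samples per group to be tested.
    """
    mask = mut_mask.astype(float)
    n_samples = values.shape[1]
    n1 = mask.sum(axis=0)  # per gene
    n2 = n_samples - n1

    s1 = values @ mask
    s2 = values.sum(axis=1, keepdims=True) - s1
    sq1 = (values**2) @ mask
    sq2 = (values**2).sum(axis=1, keepdims=True) - sq1

    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = s1 / n1
        m2 = s2 / n2
        v1 = np.maximum(sq1 - n1 * m1**2, 0.0) / (n1 - 1)
        v2 = np.maximum(sq2 - n2 * m2**2, 0.0) / (n2 - 1)
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    tested = np.broadcast_to((n1 >= 2) & (n2 >= 2), t.shape).copy()
    diff = m1 - m2
    sign = np.sign(diff)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero variance in both groups: p=1 when means agree, p=0 otherwise
    zero_se = se2 == 0
    p = np.where(zero_se & (diff == 0), 1.0, p)
    p = np.where(zero_se & (diff != 0), 0.0, p)
    p = np.where(tested, p, 1.0)
    sign = np.where(tested, sign, 0.0)
    return p, sign, tested


def genome_wide_counts(
    bundle,
    genes,
    modality: str = "methylation",
    alpha: float = 0.01,
    log_expression: bool = True,
) -> pd.DataFrame:
    """Differential counts of all ``genes`` against a cohort in one pass.

    For methylation, counts CpG sites significantly hyper/hypo-methylated in
    mutated vs wild-type samples (two one-sided Wilcoxon tests, each at
    ``alpha``); for expression, genes up/down-regulated (Welch t at ``alpha``,
    split by the sign of the mean difference), excluding each mutated gene
    from its own target count. Returns a DataFrame indexed by gene with
    columns ``n_plus``, ``n_minus``, ``n_m``, ``n_mutated``, ``n_skipped``.

    Expression values are log1p-transformed before testing by default:
    expression is strongly right-skewed, and with the very small mutated
    groups typical here a t-test on the raw scale is directionally biased
    toward "down". The transform is monotone, so up/down labels keep their
    meaning; disable with ``log_expression=False``.
    """
    genes = list(genes)
    if modality == "methylation":
        samples = bundle.methylation_samples
        values = bundle.methylation[samples].to_numpy(dtype=float)
    elif modality == "expression":
        samples = bundle.expression_samples
        values = bundle.expression[samples].to_numpy(dtype=float)
        if log_expression:
            values = np.log1p(values)
    else:
        raise ValueError(f"unknown modality: {modality!r}")

    missing = [g for g in genes if g not in bundle.mutation.columns]
    if missing:
        raise KeyError(f"genes absent from mutation matrix: {missing[:5]}")
    mut = bundle.mutation.loc[samples, genes].to_numpy(dtype=float)
    n_mutated = mut.sum(axis=0).astype(int)
    if (n_mutated == 0).any():
        bad = [g for g, n in zip(genes, n_mutated) if n == 0]
        raise ValueError(
            f"genes with no mutated sample in cohort {bundle.cohort_id}: {bad[:5]}"
        )

    if modality == "methylation":
        if len(samples) > _ASYMPTOTIC_MIN_SAMPLES:
            p_greater, p_less, tested = _ranksum_pvalues(values, mut)
        else:
            p_greater, p_less, tested = _scalar_site_loop(values, mut)
        n_plus = ((p_greater < alpha) & tested).sum(axis=0)
        n_minus = ((p_less < alpha) & tested).sum(axis=0)
    else:
        p, sign, tested = _welch_pvalues(values, mut)
        sig = (p < alpha) & tested
        # a driver never counts itself among its dysregulated targets
        feat_index = {f: i for i, f in enumerate(bundle.expression.index)}
        for j, g in enumerate(genes):
            i = feat_index.get(g)
            if i is not None:
                sig[i, j] = False
        n_plus = (sig & (sign > 0)).sum(axis=0)
        n_minus = (sig & (sign < 0)).sum(axis=0)

    n_skipped = (~tested).sum(axis=0)
    return pd.DataFrame(
        {
            "n_plus": n_plus.astype(int),
            "n_minus": n_minus.astype(int),
            "n_m": (n_plus + n_minus).astype(int),
            "n_mutated": n_mutated,
            "n_skipped": n_skipped.astype(int),
        },
        index=pd.Index(genes, name="gene"),
    )


def _scalar_site_loop(values, mut):
    """Per-site scalar tests for small cohorts (exact where applicable)."""
    n_sites = values.shape[0]
    n_genes = mut.shape[1]
    p_greater = np.ones((n_sites, n_genes))
    p_less = np.ones((n_sites, n_genes))
    tested = np.zeros((n_sites, n_genes), dtype=bool)
    for j in range(n_genes):
        is_mut = mut[:, j] > 0
        for s in range(n_sites):
            row = values[s]
            ok = ~np.isnan(row)
            x = row[ok & is_mut]
            y = row[ok & ~is_mut]
            if x.size == 0 or y.size == 0:
                continue
            tested[s, j] = True
            p_greater[s, j], p_less[s, j] = wilcoxon_site_test(x, y)
    return p_greater, p_less, tested


def diff_methylation_count(bundle, gene: str, alpha_site: float = 0.01) -> DiffCount:
    """Genome-wide differential-methylation count for one gene in one cohort.

    ``S+`` = sites with one-sided p (mutated greater) below ``alpha_site``;
    ``S-`` the mirror. No site-level multiplicity adjustment by design.
    """
    row = genome_wide_counts(bundle, [gene], "methylation", alpha_site).iloc[0]
    return DiffCount(gene, bundle.cohort_id, int(row.n_plus), int(row.n_minus), "methylation")


def diff_expression_count(bundle, gene: str, alpha_gene: float = 0.05) -> DiffCount:
    """Genome-wide differential-expression count (|G+|, |G-|) for one gene."""
    row = genome_wide_counts(bundle, [gene], "expression", alpha_gene).iloc[0]
    return DiffCount(gene, bundle.cohort_id, int(row.n_plus), int(row.n_minus), "expression")
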