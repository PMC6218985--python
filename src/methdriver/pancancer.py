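"""Pan-cancer aggregation: resampling p-values, grouped FDR, driver calls.

A candidate gene mutated in the cohort set A_i (>= 5 mutated samples with
the relevant data) is scored by the total differential count summed over
A_i. Its pan-cancer p-value compares that total with B resampled sums of
|A_i| draws (uniform, with replacement) from the null pool:

    p_i = (1/B) * sum_b I( sum_k n_{i,k} <= sum_j n_{r_{b,j}} )

Benjamini-Hochberg adjustment is applied *within groups of genes sharing
|A_i|* -- genes mutated in more cohorts accumulate larger totals by
construction, so stratifying keeps the comparison fair -- and drivers are
the genes with adjusted p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .nullpool import NullPool

__all__ = [
    "DriverCall",
    "eligible_cohorts",
    "resample_null_sums",
    "pan_cancer_p",
    "pan_cancer_p_exact",
    "bh_adjust_grouped",
    "call_drivers",
]

_MAX_EXACT_SUPPORT = 20_000_000  # convolution support cap for the exact path


@dataclass(frozen=True)
class DriverCall:
    """Pan-cancer call for one candidate gene.

    ``direction`` summarizes the per-cohort calls: "both" when significant
    cohorts disagree in sign, the common sign otherwise, "none" when no
    cohort is individually significant (a gene can still be a driver then --
    the pan-cancer evidence is the total count, not any single cohort).
    """

    gene: str
    modality: str
    A_i: frozenset
    T_i: frozenset
    T_plus: frozenset
    T_minus: frozenset
    observed_sum: int
    p_i: float
    p_adj: float
    direction: str  # both | hyper | hypo | up | down | none
    is_driver: bool
    p_ik: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.T_plus | self.T_minus != self.T_i:
            raise ValueError("T_i must equal T_plus | T_minus")
        if not self.T_i <= self.A_i:
            raise ValueError("T_i must be a subset of A_i")


def eligible_cohorts(
    cohorts, gene: str, min_mutated: int = 5, modality: str = "methylation"
) -> set[str]:
    """A_i: cohorts where ``gene`` is mutated in >= min_mutated samples
    that have the modality's data."""
    return {
        b.cohort_id
        for b in cohorts
        if b.n_mutated(gene, modality) >= min_mutated
    }


def resample_null_sums(
    pool: NullPool, m: int, B: int, rng: np.random.Generator
) -> np.ndarray:
    """B sums of m uniform-with-replacement draws from the pool, sorted."""
    if B < 1 or m < 1:
        raise ValueError("B and m must be >= 1")
    values = pool.values
    sums = np.zeros(B, dtype=np.int64)
    chunk = max(1, min(B, 50_000_000 // max(m, 1)))
    for start in range(0, B, chunk):
        stop = min(start + chunk, B)
        idx = rng.integers(0, values.size, size=(stop - start, m))
        sums[start:stop] = values[idx].sum(axis=1)
    sums.sort()
    return sums


def pan_cancer_p(
    observed_sum: int,
    pool: NullPool,
    m: int,
    B: int = 1_000_000,
    seed: int | None = None,
    null_sums: np.ndarray | None = None,
) -> float:
    """Monte-Carlo pan-cancer p: fraction of resampled sums >= observed.

    ``null_sums`` lets callers reuse one sorted resample across all genes
    sharing the same |A_i| (statistically identical under the null and far
    cheaper); otherwise B fresh resamples are drawn with ``seed``.
    """
    if null_sums is None:
        rng = np.random.default_rng(seed)
        null_sums = resample_null_sums(pool, m, B, rng)
    n_below = np.searchsorted(null_sums, observed_sum, side="left")
    return float((null_sums.size - n_below) / null_sums.size)


def pan_cancer_p_exact(observed_sum: int, pool: NullPool, m: int) -> float:
    """Exact P(sum of m i.i.d. pool draws >= observed_sum).

    Computed by m-fold convolution of the pool's empirical probability mass
    function over the integer count support; refuses supports too large to
    enumerate (use the Monte-Carlo path instead).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    values = pool.values
    max_sum = int(values.max()) * m
    if max_sum > _MAX_EXACT_SUPPORT:
        raise ValueError(
            f"support of size {max_sum} too large for exact convolution; "
            "use pan_cancer_p (Monte-Carlo)"
        )
    pmf = np.bincount(values) / values.size
    total = pmf.copy()
    for _ in range(m - 1):
        total = np.convolve(total, pmf)
    if observed_sum <= 0:
        return 1.0
    if observed_sum > max_sum:
        return 0.0
    return float(total[observed_sum:].sum())


def bh_adjust_grouped(
    p_values: dict[str, float], groups: dict[str, int]
) -> dict[str, float]:
    """Benjamini-Hochberg step-up within strata of equal group label.

    ``groups`` maps each gene to its stratum (|A_i|); the adjustment runs
    independently per stratum, is monotone within each, and caps at 1.
    """
    adjusted: dict[str, float] = {}
    frame = pd.DataFrame(
        {"p": pd.Series(p_values), "group": pd.Series(groups)}
    ).dropna()
    if ((frame["p"] < 0) | (frame["p"] > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    for _, sub in frame.groupby("group"):
        adj = multipletests(sub["p"].to_numpy(), method="fdr_bh")[1]
        adjusted.update(dict(zip(sub.index, adj)))
    return adjusted


def _summarize_direction(t_plus: set, t_minus: set, modality: str) -> str:
    plus, minus = ("up", "down") if modality == "expression" else ("hyper", "hypo")
    if t_plus and t_minus:
        return "both"
    if t_plus:
        return plus
    if t_minus:
        return minus
    return "none"


def call_drivers(
    cancer_calls,
    pan_p: dict[str, float],
    p_adj: dict[str, float],
    eligible: dict[str, set],
    observed_sums: dict[str, int],
    alpha: float = 0.05,
    alpha_cohort: float = 0.05,
    modality: str = "methylation",
) -> list[DriverCall]:
    """Assemble per-gene driver calls from the per-cohort and pan-cancer stages.

    ``cancer_calls`` is an iterable of CancerLevelCall; a gene appearing in
    ``pan_p`` without any per-cohort call is an inconsistency and raises.
    """
    by_gene: dict[str, list] = {}
    for call in cancer_calls:
        by_gene.setdefault(call.gene, []).append(call)

    out = []
    for gene, p_i in pan_p.items():
        calls = by_gene.get(gene)
        if not calls:
            raise ValueError(f"gene {gene} has a pan-cancer p but no per-cohort calls")
        t_plus = {
            c.cohort for c in calls if c.p_ik < alpha_cohort and c.n_plus > c.n_minus
        }
        t_minus = {
            c.cohort for c in calls if c.p_ik < alpha_cohort and c.n_plus <= c.n_minus
        }
        t_i = t_plus | t_minus
        out.append(
            DriverCall(
                gene=gene,
                modality=modality,
                A_i=frozenset(eligible[gene]),
                T_i=frozenset(t_i),
                T_plus=frozenset(t_plus),
                T_minus=frozenset(t_minus),
                observed_sum=int(observed_sums[gene]),
                p_i=float(p_i),
                p_adj=float(p_adj[gene]),
                direction=_summarize_direction(t_plus, t_minus, modality),
                is_driver=bool(p_adj[gene] < alpha),
                p_ik={c.cohort: c.p_ik for c in calls},
            )
        )
    return out


def calls_to_frame(calls: list[DriverCall], B: int | None = None) -> pd.DataFrame:
    """Tabular view of driver calls (one row per gene)."""
    rows = []
    for c in sorted(calls, key=lambda c: (c.p_adj, c.gene)):
        rows.append(
            {
                "gene": c.gene,
                "modality": c.modality,
                "n_A": len(c.A_i),
                "n_T": len(c.T_i),
                "T_plus": ",".join(sorted(c.T_plus)),
                "T_minus": ",".join(sorted(c.T_minus)),
                "observed_sum": c.observed_sum,
                "p": c.p_i,
                "p_adj": c.p_adj,
                "direction": c.direction if c.T_i else "NA",
                "is_driver": c.is_driver,
                "B": B if B is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)
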