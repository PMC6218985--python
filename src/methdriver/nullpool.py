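"""Empirical null from passenger mutations, and per-cancer driver calls.

The significance of a candidate driver's genome-wide differential count is
judged against counts computed for *passenger* genes -- recurrently mutated
genes not on the candidate list, which are assumed to have no genome-wide
methylation/expression effect. Running the identical counting procedure for
every (passenger gene, cohort) pair yields the "null pool"; the per-cancer
p-value of a candidate is simply the fraction of pool counts at least as
large as the observed one:

    p_{i,k} = (1/|pool|) * sum_j I(n^m_{i,k} <= n^m_j)

A candidate is then classified per cohort as genome-wide hyper-methylated if
p_{i,k} < 0.05 and |S+| > |S-|, hypo-methylated if p_{i,k} < 0.05 and
|S+| <= |S-| (ties go to hypo), and unclassified otherwise; expression works
the same way with up/down.

A sanity-check alternative null -- randomly splitting a cohort's samples into
pseudo-mutated/wild-type groups at 5-40% mutated -- is also provided; it does
not capture whatever genome-wide signal real passenger mutations carry, which
is exactly why the passenger pool is the preferred null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .site_stats import genome_wide_counts, _ranksum_pvalues, _scalar_site_loop, _ASYMPTOTIC_MIN_SAMPLES

__all__ = [
    "NullPool",
    "CancerLevelCall",
    "select_null_genes",
    "build_null_pool",
    "empirical_p_per_cancer",
    "classify_direction",
    "random_split_null",
]


@dataclass(frozen=True)
class NullPool:
    """Differential counts of passenger genes with (gene, cohort) provenance."""

    table: pd.DataFrame  # columns: gene, cohort, modality, n_m
    modality: str

    def __post_init__(self):
        if len(self.table) == 0:
            raise ValueError("null pool is empty")
        if (self.table["n_m"] < 0).any():
            raise ValueError("null counts must be non-negative")

    @property
    def values(self) -> np.ndarray:
        return self.table["n_m"].to_numpy(dtype=np.int64)

    @property
    def size(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "NullPool":
        table = pd.read_csv(path, sep="\t")
        modality = table["modality"].iloc[0] if len(table) else "methylation"
        return cls(table=table, modality=modality)


@dataclass(frozen=True)
class CancerLevelCall:
    """Per (gene, cohort) empirical p and direction call."""

    gene: str
    cohort: str
    p_ik: float
    direction: str  # hyper | hypo | up | down | none
    n_plus: int
    n_minus: int


def select_null_genes(
    cohorts,
    cdg_list,
    min_mutated: int = 5,
    top_k: int = 500,
    modality: str = "methylation",
) -> dict[str, list[str]]:
    """Pick the passenger genes that feed the null pool, per cohort.

    Within each cohort: genes mutated in at least ``min_mutated`` samples
    having ``modality`` data, minus the candidate-driver list, keeping only
    the ``top_k`` most frequently mutated (ties at the cutoff broken by
    gene identifier, so the choice is order-independent).
    """
    if min_mutated < 1:
        raise ValueError("min_mutated must be >= 1")
    cdgs = set(cdg_list)
    selected: dict[str, list[str]] = {}
    for bundle in cohorts:
        samples = (
            bundle.methylation_samples
            if modality == "methylation"
            else bundle.expression_samples
        )
        counts = bundle.mutation.loc[samples].sum(axis=0)
        eligible = counts[(counts >= min_mutated) & ~counts.index.isin(cdgs)]
        order = sorted(eligible.items(), key=lambda kv: (-kv[1], kv[0]))
        selected[bundle.cohort_id] = [g for g, _ in order[:top_k]]
    if all(len(v) == 0 for v in selected.values()):
        raise ValueError("no null genes selected in any cohort")
    return selected


def build_null_pool(
    cohorts,
    null_genes: dict[str, list[str]],
    modality: str = "methylation",
    alpha: float = 0.01,
) -> NullPool:
    """Run the genome-wide counting for every (null gene, cohort) pair."""
    frames = []
    for bundle in cohorts:
        genes = null_genes.get(bundle.cohort_id, [])
        if not genes:
            continue
        counts = genome_wide_counts(bundle, genes, modality, alpha)
        frames.append(
            pd.DataFrame(
                {
                    "gene": counts.index,
                    "cohort": bundle.cohort_id,
                    "modality": modality,
                    "n_m": counts["n_m"].to_numpy(),
                }
            )
        )
    if not frames:
        raise ValueError("null gene selection empty for every cohort")
    table = pd.concat(frames, ignore_index=True).sort_values(
        ["cohort", "gene"], kind="stable", ignore_index=True
    )
    return NullPool(table=table, modality=modality)


def empirical_p_per_cancer(observed_n_m: int, pool: NullPool) -> float:
    """Fraction of pool counts >= the observed count (inclusive).

    Can be exactly 0 when the observation exceeds the whole pool; callers
    report such values with a "<1/pool_size" floor annotation.
    """
    return float((pool.values >= observed_n_m).mean())


def classify_direction(
    p_ik: float,
    n_plus: int,
    n_minus: int,
    alpha_cohort: float = 0.05,
    modality: str = "methylation",
) -> str:
    """Genome-wide direction call for one (gene, cohort).

    Ties (|S+| == |S-|) fall in the hypo/down branch per the '<=' in the
    classification rule.
    """
    if n_plus < 0 or n_minus < 0:
        raise ValueError("counts must be non-negative")
    if p_ik >= alpha_cohort:
        return "none"
    plus, minus = ("up", "down") if modality == "expression" else ("hyper", "hypo")
    return plus if n_plus > n_minus else minus


def random_split_null(
    bundle,
    pct_range=range(5, 41),
    reps: int = 10,
    alpha: float = 0.01,
    seed: int = 0,
    modality: str = "methylation",
) -> list[int]:
    """Differential counts between random pseudo-mutated / wild-type splits.

    For each percentage in ``pct_range`` (default 5..40 inclusive) and each
    of ``reps`` repetitions, round(pct% of samples) samples (at least 1) are
    relabelled pseudo-mutated and the genome-wide count is computed; the
    defaults give 36 x 10 = 360 values per cohort.
    """
    samples = (
        bundle.methylation_samples
        if modality == "methylation"
        else bundle.expression_samples
    )
    n = len(samples)
    rng = np.random.default_rng(seed)
    pcts = list(pct_range)
    n_mut_by_pct = [max(1, int(round(pct / 100 * n))) for pct in pcts]
    if n == 0 or max(n_mut_by_pct) >= n:
        raise ValueError(
            "too few samples: every split must leave at least one "
            "pseudo-mutated and one wild-type sample"
        )

    masks = np.zeros((n, len(pcts) * reps), dtype=np.int8)
    col = 0
    for pct, n_mut in zip(pcts, n_mut_by_pct):
        for _ in range(reps):
            idx = rng.choice(n, size=n_mut, replace=False)
            masks[idx, col] = 1
            col += 1

    if modality == "methylation":
        values = bundle.methylation[samples].to_numpy(dtype=float)
        if n > _ASYMPTOTIC_MIN_SAMPLES:
            p_greater, p_less, tested = _ranksum_pvalues(values, masks)
        else:
            p_greater, p_less, tested = _scalar_site_loop(values, masks)
        counts = (
            ((p_greater < alpha) & tested).sum(axis=0)
            + ((p_less < alpha) & tested).sum(axis=0)
        )
    else:
        from .site_stats import _welch_pvalues

        values = bundle.expression[samples].to_numpy(dtype=float)
        p, _, tested = _welch_pvalues(values, masks)
        counts = ((p < alpha) & tested).sum(axis=0)
    return [int(c) for c in counts]
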