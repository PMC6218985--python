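"""Model/Results interface for the pan-cancer driver analysis.

`PanCancerDriverModel` holds the cohorts and candidate list;
``fit(modality=...)`` runs the full procedure for one data modality --
genome-wide differential counting, passenger null pool, per-cancer empirical
p-values and direction calls, pan-cancer resampling p-values, grouped BH
adjustment -- and returns a `DriverResults` with the calls, the pool, and a
``summary()`` table. Downstream pattern and enrichment analyses combine a
methylation fit and an expression fit.

Typical use::

    model = PanCancerDriverModel(cohorts, candidates)
    mdg = model.fit(modality="methylation", B=100_000, seed=7)
    edg = model.fit(modality="expression", B=100_000, seed=7)
    print(mdg.summary())
    patterns = model.pattern_analysis(mdg, edg, promoter_map)
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .nullpool import (
    CancerLevelCall,
    NullPool,
    build_null_pool,
    classify_direction,
    empirical_p_per_cancer,
    select_null_genes,
)
from .pancancer import (
    DriverCall,
    bh_adjust_grouped,
    call_drivers,
    calls_to_frame,
    eligible_cohorts,
    resample_null_sums,
)
from .patterns import (
    PatternResult,
    cross_cohort_consistency,
    expression_direction_calls,
    identify_common_targets,
    pattern_tests,
    promoter_methylation_calls,
    regulator_enrichment,
)
from .site_stats import genome_wide_counts

logger = logging.getLogger(__name__)

__all__ = ["PanCancerDriverModel", "DriverResults"]


class PanCancerDriverModel:
    """Pan-cancer mutation-methylation/expression association model.

    Parameters
    ----------
    cohorts : list of CohortBundle
        One bundle per tumor type (already QC-filtered).
    candidates : list of str
        Candidate cancer driver genes (from external recurrence analysis).
    min_mutated : int
        Minimum mutated samples with modality data for a (gene, cohort) to
        enter the analysis; also applied to null-gene selection.
    alpha_site, alpha_gene : float
        Site-level Wilcoxon level (methylation) and gene-level t-test level
        (expression) defining the differential counts.
    alpha_cohort : float
        Per-cancer empirical-p level for the direction classification.
    top_k_null : int
        Cap on null genes per cohort (most frequently mutated first).
    """

    def __init__(
        self,
        cohorts,
        candidates,
        min_mutated: int = 5,
        alpha_site: float = 0.01,
        alpha_gene: float = 0.05,
        alpha_cohort: float = 0.05,
        top_k_null: int = 500,
    ):
        self.cohorts = list(cohorts)
        self.candidates = list(candidates)
        if len(set(self.candidates)) != len(self.candidates):
            raise ValueError("duplicate candidate genes")
        self.min_mutated = min_mutated
        self.alpha_site = alpha_site
        self.alpha_gene = alpha_gene
        self.alpha_cohort = alpha_cohort
        self.top_k_null = top_k_null

    @classmethod
    def from_directory(cls, directory, candidates, **kwargs):
        """Build from a directory of ``<cohort>.{mutation,methylation,expression}.tsv``."""
        from pathlib import Path

        from .io import load_cohort

        directory = Path(directory)
        cohort_ids = sorted(
            p.name.removesuffix(".mutation.tsv")
            for p in directory.glob("*.mutation.tsv")
        )
        cohorts = [
            load_cohort(
                cid,
                directory / f"{cid}.mutation.tsv",
                directory / f"{cid}.methylation.tsv",
                directory / f"{cid}.expression.tsv",
            )
            for cid in cohort_ids
        ]
        return cls(cohorts, candidates, **kwargs)

    def _site_alpha(self, modality: str) -> float:
        return self.alpha_site if modality == "methylation" else self.alpha_gene

    def fit(
        self,
        modality: str = "methylation",
        B: int = 1_000_000,
        seed: int | None = None,
        null_pool: NullPool | None = None,
    ) -> "DriverResults":
        """Run the full pipeline for one modality and return the results.

        ``B`` is the number of resampled null sums for the pan-cancer p;
        resamples are drawn once per |A_i| stratum and shared by the genes in
        it. ``null_pool`` may be supplied to reuse a previously built pool.
        """
        if modality not in ("methylation", "expression"):
            raise ValueError(f"unknown modality: {modality!r}")
        alpha = self._site_alpha(modality)

        eligible = {
            g: eligible_cohorts(self.cohorts, g, self.min_mutated, modality)
            for g in self.candidates
        }
        dropped = sorted(g for g, a in eligible.items() if not a)
        if dropped:
            logger.info(
                "%d candidates mutated in <%d samples everywhere, dropped: %s",
                len(dropped), self.min_mutated, dropped[:10],
            )
        eligible = {g: a for g, a in eligible.items() if a}
        if not eligible:
            raise ValueError("no candidate gene is eligible in any cohort")

        if null_pool is None:
            null_genes = select_null_genes(
                self.cohorts, self.candidates, self.min_mutated,
                self.top_k_null, modality,
            )
            null_pool = build_null_pool(self.cohorts, null_genes, modality, alpha)

        # per-cohort differential counts for every eligible (gene, cohort)
        counts: dict[tuple[str, str], tuple[int, int]] = {}
        for bundle in self.cohorts:
            genes = sorted(g for g, a in eligible.items() if bundle.cohort_id in a)
            if not genes:
                continue
            frame = genome_wide_counts(bundle, genes, modality, alpha)
            for g, row in frame.iterrows():
                counts[(g, bundle.cohort_id)] = (int(row.n_plus), int(row.n_minus))

        cancer_calls = []
        for (g, c), (n_plus, n_minus) in counts.items():
            p_ik = empirical_p_per_cancer(n_plus + n_minus, null_pool)
            cancer_calls.append(
                CancerLevelCall(
                    gene=g,
                    cohort=c,
                    p_ik=p_ik,
                    direction=classify_direction(
                        p_ik, n_plus, n_minus, self.alpha_cohort, modality
                    ),
                    n_plus=n_plus,
                    n_minus=n_minus,
                )
            )

        observed_sums = {
            g: sum(sum(counts[(g, c)]) for c in a) for g, a in eligible.items()
        }

        # pan-cancer p: one sorted resample per |A_i| stratum, shared
        rng = np.random.default_rng(seed)
        strata = sorted({len(a) for a in eligible.values()})
        sums_by_m = {m: resample_null_sums(null_pool, m, B, rng) for m in strata}
        pan_p = {}
        for g, a in eligible.items():
            null_sums = sums_by_m[len(a)]
            below = np.searchsorted(null_sums, observed_sums[g], side="left")
            pan_p[g] = float((B - below) / B)

        p_adj = bh_adjust_grouped(pan_p, {g: len(a) for g, a in eligible.items()})
        calls = call_drivers(
            cancer_calls, pan_p, p_adj, eligible, observed_sums,
            alpha=0.05, alpha_cohort=self.alpha_cohort, modality=modality,
        )
        return DriverResults(
            model=self,
            modality=modality,
            calls=calls,
            cancer_calls=cancer_calls,
            null_pool=null_pool,
            B=B,
            dropped_candidates=dropped,
        )

    # -- downstream -------------------------------------------------------

    def pattern_analysis(
        self,
        methylation_results: "DriverResults",
        expression_results: "DriverResults",
        promoter_map: dict[str, list[str]],
        drivers=None,
    ) -> list[PatternResult]:
        """Joint promoter-methylation x expression patterns for overlapping drivers.

        Runs on every gene called a driver in both modalities (or the given
        ``drivers``), over the cohorts in T_i intersect E_i, and adds the
        pairwise cross-cohort consistency medians (over the modality's
        eligible cohorts).
        """
        mdg = {c.gene: c for c in methylation_results.calls if c.is_driver}
        edg = {c.gene: c for c in expression_results.calls if c.is_driver}
        if drivers is None:
            drivers = sorted(set(mdg) & set(edg))
        by_id = {b.cohort_id: b for b in self.cohorts}
        out = []
        for g in drivers:
            cohorts_used = sorted(mdg[g].T_i & edg[g].T_i)
            if not cohorts_used:
                logger.info("driver %s has empty T_i∩E_i; skipped", g)
                continue
            dm_calls, de_calls = {}, {}
            for c in cohorts_used:
                dm_calls[c] = promoter_methylation_calls(
                    by_id[c], g, promoter_map, self.alpha_site
                )
                de_calls[c], _ = expression_direction_calls(
                    by_id[c], g, self.alpha_gene
                )
            result = pattern_tests(g, cohorts_used, dm_calls, de_calls)

            # pairwise consistency over the cohorts where the gene is eligible
            meth_sets, expr_sets = {}, {}
            for c in sorted(mdg[g].A_i):
                calls = dm_calls.get(c) or promoter_methylation_calls(
                    by_id[c], g, promoter_map, self.alpha_site
                )
                meth_sets[c] = {t for t, d in calls.items() if d != "none"}
            for c in sorted(edg[g].A_i):
                calls = de_calls.get(c)
                if calls is None:
                    calls, _ = expression_direction_calls(by_id[c], g, self.alpha_gene)
                expr_sets[c] = {t for t, d in calls.items() if d != "none"}
            n_meth_univ = len(promoter_map) - (1 if g in promoter_map else 0)
            n_expr_univ = len(by_id[cohorts_used[0]].expression.index) - 1
            result.p_methyl_median = cross_cohort_consistency(meth_sets, n_meth_univ)
            result.p_exp_median = cross_cohort_consistency(expr_sets, n_expr_univ)
            out.append(result)
        return out

    def enrichment_analysis(
        self,
        methylation_results: "DriverResults",
        regulator_lists,
        drivers=None,
    ) -> pd.DataFrame:
        """Chromatin-regulator enrichment among a driver's common targets.

        For each driver (default: called MDGs with |T_i| >= 1): targets
        dysregulated (t-test p < alpha_gene) in *all* T_i cohorts, then
        hypergeometric enrichment of list A and list B among them, within
        the expression universe shared by those cohorts.
        """
        mdg = {c.gene: c for c in methylation_results.calls if c.is_driver}
        if drivers is None:
            drivers = sorted(g for g, c in mdg.items() if c.T_i)
        by_id = {b.cohort_id: b for b in self.cohorts}
        rows = []
        for g in drivers:
            t_i = sorted(mdg[g].T_i)
            per_cohort_p = {}
            universe = None
            for c in t_i:
                _, pvals = expression_direction_calls(by_id[c], g, self.alpha_gene)
                per_cohort_p[c] = pvals
                genes = set(pvals)
                universe = genes if universe is None else universe & genes
            targets = identify_common_targets(per_cohort_p, t_i, self.alpha_gene)
            lists = regulator_lists.restrict(universe)
            n2, p_a = regulator_enrichment(targets, lists.list_a, universe)
            n3, p_b = regulator_enrichment(targets, lists.list_b, universe)
            rows.append(
                {
                    "gene": g,
                    "n_T": len(t_i),
                    "N1": len(targets),
                    "N2": n2,
                    "N3": n3,
                    "p_value_A": p_a,
                    "p_value_B": p_b,
                }
            )
        return pd.DataFrame(rows)

    def interactor_enrichment(
        self,
        interactors: dict[str, set],
        regulator_lists,
        universe,
    ) -> pd.DataFrame:
        """Enrichment of list-A regulators among each driver's physical interactors.

        ``interactors`` maps driver -> set of interacting genes (an external
        input, e.g. from a protein-interaction database export).
        """
        rows = []
        for g, partners in interactors.items():
            lists = regulator_lists.restrict(universe)
            n5, p_a = regulator_enrichment(partners, lists.list_a, universe)
            rows.append(
                {
                    "gene": g,
                    "N4": len(set(partners) & set(universe)),
                    "N5": n5,
                    "p_value_A": p_a,
                }
            )
        return pd.DataFrame(rows)


class DriverResults:
    """Fitted results: driver calls for one modality.

    Attributes
    ----------
    calls : list of DriverCall
    cancer_calls : list of CancerLevelCall
    null_pool : NullPool
    """

    def __init__(self, model, modality, calls, cancer_calls, null_pool, B,
                 dropped_candidates=()):
        self.model = model
        self.modality = modality
        self.calls = calls
        self.cancer_calls = cancer_calls
        self.null_pool = null_pool
        self.B = B
        self.dropped_candidates = list(dropped_candidates)

    @property
    def drivers(self) -> list[str]:
        """Genes with adjusted pan-cancer p < 0.05."""
        return sorted(c.gene for c in self.calls if c.is_driver)

    @property
    def frame(self) -> pd.DataFrame:
        return calls_to_frame(self.calls, B=self.B)

    @property
    def cancer_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": c.gene,
                "cohort": c.cohort,
                "n_plus": c.n_plus,
                "n_minus": c.n_minus,
                "n_m": c.n_plus + c.n_minus,
                "p_ik": c.p_ik,
                "direction": c.direction,
                "pool_size": self.null_pool.size,
            }
            for c in self.cancer_calls
        ]
        return pd.DataFrame(rows).sort_values(["gene", "cohort"], ignore_index=True)

    def summary(self) -> str:
        kind = "MDG" if self.modality == "methylation" else "EDG"
        frame = self.frame
        lines = [
            f"Pan-cancer {kind} analysis",
            f"  cohorts: {len(self.model.cohorts)}  candidates tested: {len(self.calls)}"
            f"  (dropped: {len(self.dropped_candidates)})",
            f"  null pool size: {self.null_pool.size}  resamples B: {self.B}",
            f"  drivers called (adj p < 0.05): {len(self.drivers)}",
            "",
            frame.drop(columns=["modality", "B"]).to_string(index=False),
        ]
        return "\n".join(lines)
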