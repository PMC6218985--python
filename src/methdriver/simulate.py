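"""Synthetic multi-cohort mutation / methylation / expression generator.

The generator reproduces the statistical structure the pan-cancer driver
analysis assumes, so every downstream stage can be exercised and calibrated
without external data:

* CpG beta values are drawn from a two-component beta mixture with a per-site
  high-mode weight, giving the bimodal enrichment near 0 and 1 typical of
  450K arrays.
* Mutation indicators are Bernoulli per (gene, cohort) with frequencies drawn
  uniformly from a 5-40% style range, so mutated/wild-type groups are as
  unbalanced as in tumor cohorts.
* Planted methylation drivers shift beta values of mutated samples at a
  chosen set of sites on the logit scale (values therefore stay in [0, 1]);
  planted expression drivers scale target-gene expression by a log fold
  change. Passenger genes carry no systematic effect.
* With promoter-expression coupling on, a driver's affected sites are the
  promoter CpGs of its affected target genes and the directions are linked:
  promoter hyper-methylation comes with down-regulation and vice versa, so
  the "+-"/"-+" pattern signature is planted.

Each simulated gene owns a disjoint block of ``n_sites // n_genes`` CpG
sites as its promoter (1,500 bp upstream of the TSS in the emulated data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import CohortBundle, write_cohort, write_promoter_map

__all__ = ["SimConfig", "SimTruth", "simulate_cohorts", "write_truth"]

_BETA_CLIP = (0.001, 0.999)  # clip before logit so the shift is finite


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic multi-cohort dataset.

    Defaults mirror the scale used throughout the package's calibration
    experiments: 3 cohorts of 200 tumors, a 20,000-site methylome, a
    2,000-gene transcriptome, 50 candidate drivers of which 5 shift
    methylation and 5 shift expression, and 120 passenger genes that feed
    the empirical null pool.
    """

    n_cohorts: int = 3
    samples_per_cohort: int = 200
    n_sites: int = 20_000
    n_genes: int = 2_000
    n_candidate_drivers: int = 50
    n_mdgs: int = 5
    n_edgs: int = 5
    n_passengers: int = 120
    mutation_freq_range: tuple[float, float] = (0.05, 0.40)
    # two-component beta mixture: (a, b) of the unmethylated and methylated
    # modes; the high-mode weight is uniform per site
    beta_low_shape: tuple[float, float] = (1.5, 15.0)
    beta_high_shape: tuple[float, float] = (15.0, 1.5)
    fraction_of_sites_affected: float = 0.05
    methylation_shift: float = 1.5  # logit-scale magnitude of planted shifts
    fraction_of_genes_affected: float = 0.05
    expression_log_fold: float = 1.0
    couple_promoter_expression: bool = False
    missing_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_cohorts": self.n_cohorts,
            "samples_per_cohort": self.samples_per_cohort,
            "n_sites": self.n_sites,
            "n_genes": self.n_genes,
            "n_candidate_drivers": self.n_candidate_drivers,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_mdgs", "n_edgs", "n_passengers"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_mdgs + (0 if self.couple_promoter_expression else self.n_edgs) > self.n_candidate_drivers:
            raise ValueError("planted drivers exceed the candidate list size")
        lo, hi = self.mutation_freq_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("mutation_freq_range must be ordered within [0, 1]")
        for name in (
            "fraction_of_sites_affected",
            "fraction_of_genes_affected",
            "missing_rate",
        ):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        n_mut_genes = self.n_candidate_drivers + self.n_passengers
        if n_mut_genes > self.n_genes:
            raise ValueError(
                "mutated genes (candidates + passengers) must fit in n_genes"
            )
        if self.n_mdgs > 0:
            if self.couple_promoter_expression:
                needed = round(self.fraction_of_genes_affected * self.n_genes)
            else:
                needed = round(self.fraction_of_sites_affected * self.n_sites)
            if needed < 1:
                raise ValueError(
                    "n_sites too small for the requested fraction_of_sites_affected"
                )
        if self.n_edgs > 0 and round(self.fraction_of_genes_affected * self.n_genes) < 1:
            raise ValueError(
                "n_genes too small for the requested fraction_of_genes_affected"
            )
        if int(round(self.mutation_freq_range[0] * self.samples_per_cohort)) < 1:
            raise ValueError("samples_per_cohort too small for the mutation range")


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset, for recovery testing.

    Directions are +1/-1: for methylation drivers the sign of the planted
    logit shift (hyper/hypo), for expression drivers the sign of the planted
    log fold change (up/down).
    """

    candidates: list[str]
    passengers: list[str]
    planted_mdgs: dict[str, int]
    planted_edgs: dict[str, int]
    affected_sites: dict[str, list[str]] = field(default_factory=dict)
    affected_targets: dict[str, list[str]] = field(default_factory=dict)
    promoter_map: dict[str, list[str]] = field(default_factory=dict)


def _draw_beta_matrix(rng, high_weight, low_shape, high_shape, n_samples):
    """Per-site beta mixture: (n_sites, n_samples) values in (0, 1)."""
    n_sites = high_weight.size
    is_high = rng.random((n_sites, n_samples)) < high_weight[:, None]
    low = rng.beta(low_shape[0], low_shape[1], size=(n_sites, n_samples))
    high = rng.beta(high_shape[0], high_shape[1], size=(n_sites, n_samples))
    return np.where(is_high, high, low)


def _logit_shift(beta: np.ndarray, shift: float) -> np.ndarray:
    clipped = np.clip(beta, *_BETA_CLIP)
    return expit(logit(clipped) + shift)


def simulate_cohorts(config: SimConfig) -> tuple[list[CohortBundle], SimTruth]:
    """Generate the cohorts and their ground truth.

    The same planted drivers act with the same direction and on the same
    sites/targets in every cohort (a pan-cancer effect); mutation frequencies
    are redrawn per cohort. Identical config and seed reproduce identical
    output.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_cohorts + 1)
    rng = np.random.default_rng(children[0])

    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    sites = [f"cg{i:07d}" for i in range(config.n_sites)]
    candidates = genes[: config.n_candidate_drivers]
    passengers = genes[
        config.n_candidate_drivers : config.n_candidate_drivers + config.n_passengers
    ]
    mutated_genes = candidates + passengers

    # promoter map: disjoint site blocks, one per gene
    spg = config.n_sites // config.n_genes
    promoter_map = {
        g: sites[i * spg : (i + 1) * spg] for i, g in enumerate(genes) if spg > 0
    }

    planted_mdgs = {
        g: int(rng.choice([-1, 1])) for g in candidates[: config.n_mdgs]
    }
    if config.couple_promoter_expression:
        # coupled drivers disturb both layers: promoter hyper <-> expression down
        edg_genes = candidates[: config.n_mdgs]
    else:
        edg_genes = candidates[config.n_mdgs : config.n_mdgs + config.n_edgs]
    planted_edgs: dict[str, int] = {}

    non_mutated_pool = np.array(genes[len(mutated_genes) :])
    n_targets = int(round(config.fraction_of_genes_affected * config.n_genes))
    n_aff_sites = int(round(config.fraction_of_sites_affected * config.n_sites))

    affected_sites: dict[str, list[str]] = {}
    affected_targets: dict[str, list[str]] = {}
    # per-driver effect plans: (site rows, logit shift) / (gene rows, scale)
    meth_effects: dict[str, list[tuple[list[str], float]]] = {}
    expr_effects: dict[str, list[tuple[list[str], float]]] = {}
    site_arr = np.array(sites)
    shift_mag = abs(config.methylation_shift)
    lfc_mag = abs(config.expression_log_fold)
    for g, d in planted_mdgs.items():
        if config.couple_promoter_expression:
            # both coupled signatures: one half of the targets is promoter-
            # hyper-methylated and down-regulated, the other hypo and up
            targets = list(rng.choice(non_mutated_pool, size=n_targets, replace=False))
            half = (len(targets) + 1) // 2
            first, second = targets[:half], targets[half:]
            affected_targets[g] = targets
            affected_sites[g] = [s for t in targets for s in promoter_map.get(t, [])]
            meth_effects[g] = [
                ([s for t in first for s in promoter_map.get(t, [])], d * shift_mag),
                ([s for t in second for s in promoter_map.get(t, [])], -d * shift_mag),
            ]
            expr_effects[g] = [
                (first, float(np.exp(-d * lfc_mag))),
                (second, float(np.exp(d * lfc_mag))),
            ]
            planted_edgs[g] = -d  # coupling pairing: hyper <-> down
        else:
            affected_sites[g] = list(
                rng.choice(site_arr, size=n_aff_sites, replace=False)
            )
            meth_effects[g] = [(affected_sites[g], d * shift_mag)]
    for g in edg_genes:
        if g in planted_edgs:
            continue
        d = int(rng.choice([-1, 1]))
        planted_edgs[g] = d
        affected_targets[g] = list(
            rng.choice(non_mutated_pool, size=n_targets, replace=False)
        )
        expr_effects[g] = [(affected_targets[g], float(np.exp(d * lfc_mag)))]

    # global per-site mixture weights and per-gene expression baselines are
    # shared across cohorts so a site/gene keeps its character everywhere
    high_weight = rng.random(config.n_sites)
    expr_mu = rng.normal(3.0, 1.0, size=config.n_genes)

    site_pos = {s: i for i, s in enumerate(sites)}
    gene_pos = {g: i for i, g in enumerate(genes)}

    bundles = []
    for k in range(config.n_cohorts):
        crng = np.random.default_rng(children[k + 1])
        cohort_id = f"C{k + 1:02d}"
        n = config.samples_per_cohort
        sample_ids = [f"{cohort_id}_S{j:03d}" for j in range(n)]

        lo, hi = config.mutation_freq_range
        freqs = crng.uniform(lo, hi, size=len(mutated_genes))
        mut = (crng.random((n, len(mutated_genes))) < freqs).astype(np.int8)
        mutation = pd.DataFrame(mut, index=sample_ids, columns=mutated_genes)

        beta = _draw_beta_matrix(
            crng, high_weight, config.beta_low_shape, config.beta_high_shape, n
        )
        expr = crng.lognormal(mean=expr_mu[:, None], sigma=0.5, size=(config.n_genes, n))

        for g, plans in meth_effects.items():
            carriers = np.nonzero(mutation[g].to_numpy(bool))[0]
            if carriers.size == 0:
                continue
            for site_list, shift in plans:
                if not site_list:
                    continue
                rows = [site_pos[s] for s in site_list]
                sub = beta[np.ix_(rows, carriers)]
                beta[np.ix_(rows, carriers)] = _logit_shift(sub, shift)
        for g, plans in expr_effects.items():
            carriers = np.nonzero(mutation[g].to_numpy(bool))[0]
            if carriers.size == 0:
                continue
            for target_list, scale in plans:
                if not target_list:
                    continue
                rows = [gene_pos[t] for t in target_list]
                expr[np.ix_(rows, carriers)] *= scale

        if config.missing_rate > 0:
            miss = crng.random(beta.shape) < config.missing_rate
            beta = np.where(miss, np.nan, beta)

        bundles.append(
            CohortBundle(
                cohort_id=cohort_id,
                mutation=mutation,
                methylation=pd.DataFrame(beta, index=sites, columns=sample_ids),
                expression=pd.DataFrame(expr, index=genes, columns=sample_ids),
            )
        )

    truth = SimTruth(
        candidates=candidates,
        passengers=passengers,
        planted_mdgs=planted_mdgs,
        planted_edgs=planted_edgs,
        affected_sites=affected_sites,
        affected_targets=affected_targets,
        promoter_map=promoter_map,
    )
    return bundles, truth


def write_truth(truth: SimTruth, outdir) -> Path:
    """Persist the ground truth as a TSV (gene, role, directions, sizes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for g in truth.candidates + truth.passengers:
        role = []
        if g in truth.planted_mdgs:
            role.append("mdg")
        if g in truth.planted_edgs:
            role.append("edg")
        if g in truth.passengers:
            role.append("passenger")
        rows.append(
            {
                "gene": g,
                "role": "+".join(role) or "candidate_passenger",
                "direction_methyl": truth.planted_mdgs.get(g, 0),
                "direction_expr": truth.planted_edgs.get(g, 0),
                "n_affected_sites": len(truth.affected_sites.get(g, [])),
                "n_affected_targets": len(truth.affected_targets.get(g, [])),
            }
        )
    path = outdir / "truth.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def write_simulation(bundles, truth, outdir) -> None:
    """Write cohorts, truth and promoter map in the package's TSV formats."""
    outdir = Path(outdir)
    for bundle in bundles:
        write_cohort(bundle, outdir)
    write_truth(truth, outdir)
    write_promoter_map(truth.promoter_map, Path(outdir) / "promoters.bed")
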