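"""Cohort input/output: reading, validation, methylation QC and result tables.

On-disk conventions
-------------------
All matrices are tab-delimited with the first column as the row identifier:
methylation is site x sample (beta values in [0, 1], ``NA`` for missing),
expression is gene x sample (non-negative, complete), mutation is either a
sample x gene 0/1 matrix or a MAF-like table with at least ``sample``,
``gene`` and ``variant_class`` columns. A gene counts as mutated in a sample
if any mutation record exists for the pair, regardless of variant class.

Gene lists are plain text, one symbol per line. Promoter maps are BED-like:
``chrom  start  end  gene  site_id`` (strand is ignored; sites are expected
to lie within 1,500 bp upstream of the TSS by construction of the map).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CohortBundle",
    "ValidationError",
    "load_cohort",
    "load_mutation",
    "load_matrix",
    "qc_filter_methylation",
    "write_results",
    "write_cohort",
    "read_gene_list",
    "read_promoter_map",
    "write_promoter_map",
]


class ValidationError(ValueError):
    """Raised when cohort inputs violate the format contract."""


@dataclass
class CohortBundle:
    """One tumor type's aligned mutation / methylation / expression data.

    The three matrices may cover different sample sets; the samples shared by
    mutation and methylation define the methylation-analysis set, and those
    shared by mutation and expression the expression-analysis set.
    """

    cohort_id: str
    mutation: pd.DataFrame  # samples x genes, 0/1
    methylation: pd.DataFrame  # sites x samples, beta in [0,1], NaN missing
    expression: pd.DataFrame  # genes x samples, non-negative

    methylation_samples: list[str] = field(init=False, repr=False)
    expression_samples: list[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, frame, axis in (
            ("mutation", self.mutation, 1),
            ("methylation", self.methylation, 0),
            ("expression", self.expression, 0),
        ):
            ids = frame.index if axis == 0 else frame.columns
            if ids.has_duplicates:
                raise ValidationError(f"{name}: duplicate identifiers")
        beta = self.methylation.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(beta) < 0 or np.nanmax(beta) > 1:
                raise ValidationError("methylation beta values must lie in [0, 1]")
        expr = self.expression.to_numpy(dtype=float)
        if np.isnan(expr).any():
            raise ValidationError("expression matrix contains missing values")
        if expr.size and expr.min() < 0:
            raise ValidationError("expression values must be non-negative")
        mut = self.mutation.to_numpy()
        if not np.isin(mut, (0, 1)).all():
            raise ValidationError("mutation matrix must be binary 0/1")
        mut_samples = set(self.mutation.index)
        self.methylation_samples = [
            s for s in self.methylation.columns if s in mut_samples
        ]
        self.expression_samples = [
            s for s in self.expression.columns if s in mut_samples
        ]
        if not self.methylation_samples and not self.expression_samples:
            raise ValidationError(
                f"cohort {self.cohort_id}: no sample overlaps mutation data "
                "in either methylation or expression"
            )

    def n_mutated(self, gene: str, modality: str = "methylation") -> int:
        """Mutated samples with data for ``modality``."""
        samples = (
            self.methylation_samples
            if modality == "methylation"
            else self.expression_samples
        )
        if gene not in self.mutation.columns:
            return 0
        return int(self.mutation.loc[samples, gene].sum())


def load_matrix(path) -> pd.DataFrame:
    """Read a TSV matrix with the first column as row identifier."""
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    frame.index.name = None
    frame.columns.name = None
    return frame


def load_mutation(path) -> pd.DataFrame:
    """Read mutation calls as a binary sample x gene matrix.

    Accepts either a 0/1 matrix (samples in rows) or a MAF-like long table
    with ``sample`` and ``gene`` columns, which is collapsed with the
    any-mutation rule (idempotent over repeated records).
    """
    head = pd.read_csv(path, sep="\t", nrows=1)
    cols = {c.lower() for c in head.columns}
    if {"sample", "gene"} <= cols:
        maf = pd.read_csv(path, sep="\t")
        maf.columns = [c.lower() for c in maf.columns]
        mat = (
            maf.assign(value=1)
            .pivot_table(index="sample", columns="gene", values="value", aggfunc="max")
            .fillna(0)
            .astype(int)
        )
        mat.index = mat.index.astype(str)
        mat.columns = mat.columns.astype(str)
        mat.index.name = None
        mat.columns.name = None
        return mat
    mat = load_matrix(path)
    return mat.fillna(0).astype(int)


def load_cohort(
    cohort_id: str,
    mutation_path,
    methylation_path,
    expression_path,
) -> CohortBundle:
    """Load and validate one cohort's triplet of files."""
    return CohortBundle(
        cohort_id=cohort_id,
        mutation=load_mutation(mutation_path),
        methylation=load_matrix(methylation_path),
        expression=load_matrix(expression_path),
    )


def qc_filter_methylation(
    bundle: CohortBundle,
    exclusions=(),
    max_missing: float = 0.05,
) -> tuple[CohortBundle, dict]:
    """Drop excluded CpG sites and sites with too many missing values.

    A site is removed when its missing fraction across all methylation
    samples *strictly exceeds* ``max_missing`` (default 5%), or when it
    appears in ``exclusions`` (SNP-overlapping / sex-chromosome sites).
    Returns the filtered bundle and a report of the counts removed per rule.
    """
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    meth = bundle.methylation
    excl = set(exclusions)
    excluded_mask = meth.index.isin(excl)
    missing_frac = meth.isna().mean(axis=1)
    missing_mask = (missing_frac > max_missing).to_numpy()
    keep = ~(excluded_mask | missing_mask)
    report = {
        "n_input_sites": len(meth),
        "n_excluded": int(excluded_mask.sum()),
        "n_high_missing": int(missing_mask.sum()),
        "n_kept": int(keep.sum()),
    }
    if report["n_kept"] == 0:
        dominant = (
            "site exclusion list"
            if report["n_excluded"] >= report["n_high_missing"]
            else f"missingness > {max_missing:.0%}"
        )
        raise ValidationError(f"all sites removed by QC (dominant filter: {dominant})")
    logger.info("QC %s: %s", bundle.cohort_id, report)
    filtered = CohortBundle(
        cohort_id=bundle.cohort_id,
        mutation=bundle.mutation,
        methylation=meth.loc[keep],
        expression=bundle.expression,
    )
    return filtered, report


def write_cohort(bundle: CohortBundle, outdir) -> dict[str, Path]:
    """Write a cohort bundle back to the TSV formats ``load_cohort`` reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mutation": outdir / f"{bundle.cohort_id}.mutation.tsv",
        "methylation": outdir / f"{bundle.cohort_id}.methylation.tsv",
        "expression": outdir / f"{bundle.cohort_id}.expression.tsv",
    }
    bundle.mutation.to_csv(paths["mutation"], sep="\t", index_label="sample")
    bundle.methylation.to_csv(
        paths["methylation"], sep="\t", index_label="site", na_rep="NA"
    )
    bundle.expression.to_csv(paths["expression"], sep="\t", index_label="gene")
    return paths


def _annotate_floor(frame: pd.DataFrame, p_col: str, denom_col: str) -> pd.DataFrame:
    """Add a ``<p_col>_floor`` column flagging empirical zeros as '<1/denom'."""
    out = frame.copy()
    floor = []
    for _, row in out.iterrows():
        if row[p_col] == 0 and np.isfinite(row.get(denom_col, np.nan)):
            floor.append(f"<{1.0 / row[denom_col]:.1e}")
        else:
            floor.append("")
    out[f"{p_col}_floor"] = floor
    return out


def write_results(tables: dict[str, pd.DataFrame], outdir) -> dict[str, Path]:
    """Write result tables as TSV, one file per table name.

    Driver-call tables (any table with a ``p`` column alongside a ``B`` or
    ``pool_size`` denominator column) get a companion ``p_floor`` column so
    an empirical p of exactly 0 is reported as "<1/B" next to the numeric 0.
    Floats are written with 12 significant digits so a write/read round trip
    is lossless at that precision.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, table in tables.items():
        out = table
        for p_col, denom in (("p", "B"), ("p", "pool_size"), ("p_ik", "pool_size")):
            if p_col in out.columns and denom in out.columns:
                out = _annotate_floor(out, p_col, denom)
                break
        path = outdir / f"{name}.tsv"
        out.to_csv(path, sep="\t", index=False, float_format="%.12g")
        written[name] = path
    return written


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one symbol per line; blank lines ignored."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    if len(set(genes)) != len(genes):
        raise ValidationError(f"duplicate gene symbols in {path}")
    return genes


def read_promoter_map(path) -> dict[str, list[str]]:
    """BED-like promoter map -> {gene: [site ids within the promoter]}."""
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene", "site_id"],
        dtype=str,
    )
    mapping: dict[str, list[str]] = {}
    for gene, group in frame.groupby("gene", sort=False):
        mapping[str(gene)] = list(group["site_id"])
    return mapping


def write_promoter_map(mapping: dict[str, list[str]], path) -> None:
    rows = []
    for gene, sites in mapping.items():
        for i, site in enumerate(sites):
            # synthetic coordinates: promoters occupy [0, 1500) upstream of a
            # nominal TSS; only the gene<->site pairing is meaningful
            rows.append(("chr1", i * 50, i * 50 + 2, gene, site))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
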