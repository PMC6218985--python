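import numpy as np
import pandas as pd
import pytest

from methdriver import CohortBundle


def make_bundle(
    cohort_id="C01",
    n_samples=30,
    n_sites=50,
    n_genes=20,
    mutated_genes=("gA", "gB"),
    mut_freq=0.3,
    seed=0,
):
    """Small random cohort with no planted effects."""
    rng = np.random.default_rng(seed)
    samples = [f"{cohort_id}_S{i}" for i in range(n_samples)]
    sites = [f"cg{i:04d}" for i in range(n_sites)]
    genes = [f"g{i:03d}" for i in range(n_genes)]
    mut = pd.DataFrame(
        (rng.random((n_samples, len(mutated_genes))) < mut_freq).astype(int),
        index=samples,
        columns=list(mutated_genes),
    )
    # ensure every gene has at least one mutated and one wild-type sample
    for j in range(mut.shape[1]):
        mut.iloc[0, j] = 1
        mut.iloc[1, j] = 0
    meth = pd.DataFrame(rng.random((n_sites, n_samples)), index=sites, columns=samples)
    expr = pd.DataFrame(
        rng.lognormal(3, 0.5, (n_genes, n_samples)), index=genes, columns=samples
    )
    return CohortBundle(
        cohort_id=cohort_id, mutation=mut, methylation=meth, expression=expr
    )


@pytest.fixture
def small_bundle():
    return make_bundle()
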