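import numpy as np
import pandas as pd
import pytest

from meqtlkit.simulate import (
    ScenarioSpec,
    simulate_cpg_meta,
    simulate_genotypes,
    simulate_methylation,
)


@pytest.fixture(scope="session")
def small_spec():
    return ScenarioSpec(n_samples=120, n_snps=60, n_cpgs=60, n_chroms=2, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    """Genotypes, methylation (no planted effects) and covariates, aligned."""
    rng = np.random.default_rng(small_spec.seed)
    gm = simulate_genotypes(small_spec, rng)
    cpg_meta = simulate_cpg_meta(small_spec, rng)
    mm, cov = simulate_methylation(gm, small_spec, rng, cpg_meta=cpg_meta)
    return gm, mm, cov


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def gene_fixture():
    return pd.DataFrame(
        {
            "gene_id": ["GA", "GB", "GC"],
            "chrom": ["1", "1", "2"],
            "start": [100, 1000, 50],
            "end": [500, 2000, 800],
            "biotype": ["protein_coding", "protein_coding", "protein_coding"],
        }
    )
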