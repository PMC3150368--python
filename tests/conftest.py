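import numpy as np
import pytest

from popstruct import simdata
from popstruct.genio import GenotypeMatrix, make_snp_table


@pytest.fixture(scope="session")
def two_pop_cohort():
    """Two subpopulations at clearly separable divergence (F = 0 vs 0.05)."""
    config = simdata.SimConfig(
        n_subpops=2,
        samples_per_subpop=60,
        n_snps=3000,
        subpop_F=[0.0, 0.05],
        subpop_latitude=[55.0, 65.0],
        subpop_longitude=[13.0, 19.0],
        seed=5,
    )
    return simdata.simulate_structured_genotypes(config), config


@pytest.fixture(scope="session")
def single_pop_cohort():
    """One undiverged population, 10^4 SNPs: relatedness / ROH substrate."""
    config = simdata.SimConfig(
        n_subpops=1,
        samples_per_subpop=40,
        n_snps=10_000,
        subpop_F=[0.0],
        subpop_latitude=[58.0],
        subpop_longitude=[15.0],
        seed=7,
    )
    return simdata.simulate_structured_genotypes(config), config


def random_genotypes(rng, n_samples, n_snps, maf_range=(0.05, 0.5), missing=0.0):
    p = rng.uniform(*maf_range, size=n_snps)
    values = rng.binomial(2, p, size=(n_samples, n_snps)).astype(np.int8)
    if missing > 0:
        values[rng.random(values.shape) < missing] = -1
    ids = [f"i{i}" for i in range(n_samples)]
    snp_ids = [f"s{j}" for j in range(n_snps)]
    return GenotypeMatrix(values, ids, snp_ids)


def uniform_snp_table(snp_ids, spacing=50_000, chrom="1"):
    m = len(snp_ids)
    return make_snp_table(
        snp_ids,
        [chrom] * m,
        [(j + 1) * spacing for j in range(m)],
        ["A"] * m,
        ["G"] * m,
    )
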