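import numpy as np
import pandas as pd
import pytest

from mosaicsim import FixtureSpec, GenotypeMatrix, generate_panel


def make_genotype_matrix(dosages, positions=None, chrom="1"):
    """Wrap a plain array as a GenotypeMatrix with evenly spaced positions."""
    dosages = np.asarray(dosages, dtype=np.uint8)
    n, k = dosages.shape
    if positions is None:
        positions = (np.arange(k) + 1) * 10_000
    variants = pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(positions, dtype=int),
        "ref": "A", "alt": "G",
    })
    return GenotypeMatrix(dosages, [f"s{i}" for i in range(n)], variants)


def binomial_cohort(rng, n, k, freqs=None):
    """I.i.d. Hardy-Weinberg genotypes — an LD-free null cohort."""
    if freqs is None:
        freqs = rng.uniform(0.05, 0.5, size=k)
    dosages = rng.binomial(2, freqs, size=(n, k)).astype(np.uint8)
    return make_genotype_matrix(dosages)


@pytest.fixture(scope="session")
def small_fixture():
    """100 haplotypes x 400 SNPs, one ancestry group."""
    return generate_panel(FixtureSpec(n_hap=100, n_snp=400, seed=11))


@pytest.fixture(scope="session")
def two_group_fixture():
    """Two ancestry groups from independent founder pools."""
    spec = FixtureSpec(n_hap={"A": 60, "B": 60}, n_snp=300, n_blocks=6, seed=13)
    return generate_panel(spec)
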