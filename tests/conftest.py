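import numpy as np
import pytest

from allelekit.core_io import (
    GENO_AA,
    GENO_Aa,
    GENO_aa,
    GenotypeMatrix,
    IntensityTable,
    SnpAnnotation,
)
from allelekit.synthetic import SimConfig, simulate_cohort


def make_annotation(n, chrom="1", spacing=10_000):
    return SnpAnnotation(
        np.array([f"snp{i:04d}" for i in range(n)], dtype=object),
        np.array([chrom] * n, dtype=object),
        np.arange(1, n + 1) * spacing,
        np.array(["A"] * n, dtype=object),
        np.array(["C"] * n, dtype=object),
    )


@pytest.fixture
def annotation4():
    return make_annotation(4)


@pytest.fixture
def tiny_intensity(annotation4):
    s1 = np.array([[2.0, 4.0], [1.0, 1.0], [3.0, 0.0], [5.0, 5.0]])
    s2 = np.array([[1.0, 2.0], [1.0, 1.0], [0.0, 2.0], [5.0, 5.0]])
    return IntensityTable(annotation4, ["p1", "p2"], s1, s2)


@pytest.fixture
def tiny_genotypes(annotation4):
    calls = np.array([
        [GENO_Aa, GENO_Aa],
        [GENO_Aa, GENO_AA],
        [GENO_AA, GENO_aa],
        [GENO_Aa, GENO_Aa],
    ], dtype=np.int8)
    return GenotypeMatrix(annotation4, ["p1", "p2"], calls)


@pytest.fixture(scope="session")
def small_cohort():
    """200 SNPs x 50 samples, shared by read-only tests."""
    return simulate_cohort(SimConfig(n_snps=200, n_samples=50, seed=11))
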