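import numpy as np
import pytest

from polyrisk.io import GenotypeDataset, SnpDescriptor


def make_dataset(genotypes, phenotype, snps=None, subtype=None):
    """Small helper: build a dataset from plain lists."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    if snps is None:
        snps = [
            SnpDescriptor(f"snp{j + 1:02d}", "TEST", "A", "G")
            for j in range(genotypes.shape[1])
        ]
    return GenotypeDataset(snps, genotypes, np.asarray(phenotype, np.int8), subtype)


@pytest.fixture
def toy_snps():
    return [
        SnpDescriptor("rs11574311", "WRN", "T", "C"),
        SnpDescriptor("rs2304277", "OGG1", "A", "G"),
        SnpDescriptor("rs1063147", "BLM", "C", "T"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240424)
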