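import numpy as np
import pandas as pd
import pytest

from epistax.cohort import GenotypeStudy


def make_study(genotypes, phenotype, phase=None, chrom="1"):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    meta = pd.DataFrame(
        {
            "snp": [f"snp{j}" for j in range(m)],
            "chrom": [chrom] * m,
            "pos": np.arange(m) * 1000 + 1,
            "a1": ["A"] * m,
            "a2": ["B"] * m,
        }
    )
    return GenotypeStudy(
        genotypes=genotypes,
        phenotype=np.asarray(phenotype, dtype=np.int8),
        snp_meta=meta,
        sample_ids=[f"s{i:04d}" for i in range(n)],
        phase=phase,
    )


@pytest.fixture
def tiny_study():
    geno = np.array(
        [
            [0, 1, 2],
            [1, 1, 0],
            [2, 0, 1],
            [0, 2, 0],
        ],
        dtype=np.int8,
    )
    return make_study(geno, [1, 1, 0, 0])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
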