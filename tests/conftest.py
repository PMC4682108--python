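import numpy as np
import pandas as pd
import pytest

from greml.genotype_io import GenotypeMatrix


def make_geno(dosages) -> GenotypeMatrix:
    """GenotypeMatrix from a raw dosage array with generated metadata."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    samples = pd.DataFrame({
        "fid": [f"F{i}" for i in range(n)],
        "iid": [f"I{i}" for i in range(n)],
    })
    snps = pd.DataFrame({
        "chrom": "1",
        "snp_id": [f"snp{j}" for j in range(m)],
        "cm": 0.0,
        "bp": np.arange(1, m + 1),
        "a1": "A",
        "a2": "B",
    })
    return GenotypeMatrix(dosages, samples, snps)


def random_geno(rng, n, m, missing_rate=0.0) -> GenotypeMatrix:
    d = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing_rate > 0:
        d[rng.random((n, m)) < missing_rate] = -1
    return make_geno(d)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
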