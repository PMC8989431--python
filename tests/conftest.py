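import numpy as np
import pandas as pd
import pytest

from iprs.genotype import GenotypeDataset


def make_dataset(dosages, variant_ids=None, chrom="1", alleles=("A", "B")) -> GenotypeDataset:
    """Wrap a raw dosage matrix in a GenotypeDataset with generated metadata."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    if variant_ids is None:
        variant_ids = [f"snp{j + 1}" for j in range(m)]
    variants = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chrom": chrom,
            "pos": np.arange(1, m + 1),
            "allele1": alleles[0],
            "allele2": alleles[1],
        }
    )
    ids = [f"S{i + 1}" for i in range(n)]
    samples = pd.DataFrame({"fid": ids, "iid": ids, "sex": 0, "phenotype": -9})
    return GenotypeDataset(d, variants, samples)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_dataset(rng):
    """60 samples x 8 variants with a sprinkling of missing calls."""
    maf = rng.uniform(0.2, 0.5, 8)
    d = rng.binomial(2, maf[None, :], size=(60, 8)).astype(np.int8)
    miss = rng.random((60, 8)) < 0.03
    d[miss] = -1
    return make_dataset(d)
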