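import numpy as np
import pandas as pd
import pytest

from grspipe.geno_io import GenotypeDataset


def make_dataset(dosages, chrom="1", pos=None, a1=None, a2=None, iids=None):
    """Small-dataset builder for hand-constructed genotype fixtures."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    pos = pos if pos is not None else (np.arange(m) + 1) * 1000
    a1 = a1 if a1 is not None else ["A"] * m
    a2 = a2 if a2 is not None else ["G"] * m
    iids = iids if iids is not None else [f"S{i + 1}" for i in range(n)]
    samples = pd.DataFrame({"fid": iids, "iid": iids, "father": "0",
                            "mother": "0", "sex": 1, "phenotype": -9})
    variants = pd.DataFrame({"snp": [f"rs{j + 1}" for j in range(m)],
                             "chrom": chrom, "cm": 0.0, "pos": pos,
                             "a1": a1, "a2": a2})
    return GenotypeDataset(samples, variants, dosages)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
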