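import numpy as np
import pandas as pd
import pytest

from metagwas import GenotypeMatrix


def make_genotypes(dosage, accession_ids=None, chrom=None, pos=None):
    """Small hand-built GenotypeMatrix (accessions x SNPs, NaN = missing)."""
    dosage = np.asarray(dosage, dtype=float)
    n_acc, n_snp = dosage.shape
    if accession_ids is None:
        accession_ids = [f"A{i + 1}" for i in range(n_acc)]
    if chrom is None:
        chrom = ["Chr1"] * n_snp
    if pos is None:
        pos = list(range(100, 100 + n_snp))
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"S{j + 1}" for j in range(n_snp)],
            "chrom": chrom,
            "pos": pos,
            "allele1": ["A"] * n_snp,
            "allele2": ["G"] * n_snp,
        }
    )
    return GenotypeMatrix(dosage, accession_ids, snp_map)


@pytest.fixture
def toy_qc_genotypes():
    """Four accessions, four SNPs with known (call_rate, maf, het) profiles.

    S1: [0,0,1,2] -> (1.0, 0.375, 0.25)  fails het only
    S2: [2,2,2,2] -> (1.0, 0.0, 0.0)     fails maf only
    S3: [0,1,2,NA] -> (0.75, 0.5, 1/3)   fails call rate and het
    S4: [0,0,0,2] -> (1.0, 0.25, 0.0)    survives all three rules
    """
    dosage = np.array(
        [
            [0, 2, 0, 0],
            [0, 2, 1, 0],
            [1, 2, 2, 0],
            [2, 2, np.nan, 2],
        ],
        dtype=float,
    )
    return make_genotypes(dosage)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
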