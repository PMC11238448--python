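import numpy as np
import pandas as pd
import pytest

from herdstruct.genotype_io import GenotypeDataset
from herdstruct.sim import SimConfig, simulate


def make_dataset(genotypes, positions=None, chrom="1", populations=None,
                 ids=None):
    """Build a GenotypeDataset from a raw dosage matrix."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 10_000
    if ids is None:
        ids = [f"ind{i:03d}" for i in range(n)]
    if populations is None:
        populations = ["pop1"] * n
    if np.isscalar(chrom):
        chrom = [str(chrom)] * m
    samples = pd.DataFrame({"id": ids, "population": populations})
    markers = pd.DataFrame({
        "chrom": chrom,
        "id": [f"snp{j:05d}" for j in range(m)],
        "bp": np.asarray(positions, dtype=np.int64),
        "allele_a": "A",
        "allele_b": "B",
    })
    return GenotypeDataset(samples, markers, g)


@pytest.fixture(scope="session")
def two_breed_cross():
    """Two breeds diverged at F=0.1 with F1/F2 crosses; 10k SNPs.

    Shared by the admixture parameter-recovery tests.
    """
    cfg = SimConfig(
        n_breeds=2, n_founders_per_breed=25, n_generations=4, m_snps=10_000,
        fst_per_breed=(0.1, 0.1), seed=5,
        crossbreeding_events=((1, "A", "B", 10), (2, "A", "B", 10)),
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def inbred_population():
    """One closed breed with sib matings: long autozygous tracts; 20k SNPs."""
    cfg = SimConfig(
        n_breeds=1, n_founders_per_breed=24, n_generations=6, m_snps=20_000,
        fst_per_breed=(0.3,), inbred_mating_fraction=0.3, seed=3,
    )
    return cfg, simulate(cfg)
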