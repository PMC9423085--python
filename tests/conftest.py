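import numpy as np
import pandas as pd
import pytest

from lenspop.genotypes import GenotypeMatrix, PopulationMap


def make_gm(geno, positions=None, chrom="chr1", qual=100.0, depth=20.0,
            samples=None, biallelic=True):
    """Build a GenotypeMatrix from a (samples x sites) dosage array."""
    geno = np.asarray(geno, dtype=np.int8)
    n_samples, n_sites = geno.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    if np.isscalar(chrom):
        chrom = [chrom] * n_sites
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": "A",
            "alt": "T",
            "qual": np.broadcast_to(np.asarray(qual, dtype=float), (n_sites,)).copy(),
            "mean_depth": np.broadcast_to(np.asarray(depth, dtype=float), (n_sites,)).copy(),
            "biallelic": np.broadcast_to(np.asarray(biallelic), (n_sites,)).copy(),
        }
    )
    return GenotypeMatrix(samples=list(samples), sites=sites, geno=geno)


@pytest.fixture
def toy_popmap():
    return PopulationMap.from_pairs(
        [("s0", "a"), ("s1", "a"), ("s2", "b"), ("s3", "b")]
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset shared across read-only tests."""
    from lenspop.sim import SimConfig, simulate_populations

    cfg = SimConfig(
        n_clusters=3, samples_per_cluster=15, n_chromosomes=2,
        chrom_length_bp=2_000_000, n_snps=1200, n_targets=400,
        fst_between_clusters=0.2, n_true_cnvs=8, seed=123,
    )
    return simulate_populations(cfg)
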