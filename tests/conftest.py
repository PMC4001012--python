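import numpy as np
import pytest

from epidiff.datatypes import MISSING, GenotypeDataset, TranscriptModel, VariantRecord
from epidiff.simulate import SimulationConfig, simulate_dataset


def make_dataset(calls, populations, chrom="chr1", alleles=("A", "G")):
    """Hand-build a GenotypeDataset from a samples x variants dosage list."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    variants = [
        VariantRecord(f"v{j + 1}", chrom, 100 * (j + 1), *alleles) for j in range(m)
    ]
    sample_ids = [f"s{i + 1}" for i in range(n)]
    return GenotypeDataset(
        variants=variants,
        sample_ids=sample_ids,
        population_of=dict(zip(sample_ids, populations)),
        calls=calls,
    )


@pytest.fixture
def two_pop_dataset():
    """4 + 4 samples, 3 variants, no missingness."""
    calls = [
        [2, 2, 0],
        [2, 1, 0],
        [1, 2, 1],
        [0, 2, 0],
        [1, 0, 2],
        [0, 0, 2],
        [1, 1, 2],
        [2, 0, 1],
    ]
    return make_dataset(calls, ["p1"] * 4 + ["p2"] * 4)


@pytest.fixture
def single_transcript():
    return TranscriptModel(
        gene_id="g1", transcript_id="t1", chromosome="chr1", strand="+",
        start=1000, end=2000, exons=[(1000, 1200), (1500, 2000)],
        utr5=[(1000, 1050)], utr3=[(1900, 2000)],
    )


@pytest.fixture(scope="session")
def small_simulation():
    """Session-wide small two-population simulation with planted genes."""
    config = SimulationConfig(
        n_per_population=100, n_chromosomes=4, chromosome_length=500_000,
        n_snps=1500, fst_background=0.05, fst_divergent=0.4,
        n_target_genes=20, n_divergent_genes=2, snps_per_gene=8,
        flank_snps_per_gene=2, seed=11,
    )
    return config, simulate_dataset(config)
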