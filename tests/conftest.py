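import numpy as np
import pytest

from clonepop.genotype_io import GenotypeMatrix, LocusMeta
from clonepop.synthetic import SimConfig, simulate_dataset


@pytest.fixture
def tiny_matrix() -> GenotypeMatrix:
    """Four individuals, two populations, two dinucleotide loci."""
    calls = np.array(
        [
            [[100, 102], [150, 150]],
            [[100, 102], [150, 152]],
            [[104, 104], [150, 150]],
            [[0, 0], [152, 154]],
        ]
    )
    return GenotypeMatrix(
        individuals=["a1", "a2", "b1", "b2"],
        populations=["A", "A", "B", "B"],
        loci=[LocusMeta("L1", 2), LocusMeta("L2", 2)],
        calls=calls,
    )


@pytest.fixture
def clonal_dataset():
    """Half-clonal two-deme dataset with clean calls (no mutation/missing)."""
    return simulate_dataset(
        SimConfig(n_demes=2, deme_sizes=30, clonality_c=0.5, seed=21)
    )


@pytest.fixture
def structured_dataset():
    """Three well-differentiated demes for clustering/DAPC checks."""
    return simulate_dataset(
        SimConfig(
            n_demes=3, deme_sizes=30, n_loci=8, alleles_per_locus=6,
            target_F=0.2, seed=13,
        )
    )
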