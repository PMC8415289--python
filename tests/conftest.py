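import numpy as np
import pytest

from stepstone.alignment_io import PopulationMap, SequenceAlignment


@pytest.fixture
def toy_alignment():
    """Four sequences, three haplotypes: {ACGT x2, ACGA, TCGA}."""
    return SequenceAlignment(
        ids=["a", "b", "c", "d"],
        sequences=["ACGT", "ACGT", "ACGA", "TCGA"],
        locus_name="toy",
    )


@pytest.fixture
def toy_popmap():
    return PopulationMap({"a": "P1", "b": "P1", "c": "P2", "d": "P2"})


@pytest.fixture
def fixed_difference_alignment():
    """Two populations fixed for different haplotypes (PhiST = 1)."""
    aln = SequenceAlignment(
        ids=["a1", "a2", "b1", "b2"],
        sequences=["AAAA", "AAAA", "AAAT", "AAAT"],
    )
    pm = PopulationMap({"a1": "P1", "a2": "P1", "b1": "P2", "b2": "P2"})
    return aln, pm


def random_alignment(rng: np.random.Generator, n: int, L: int) -> SequenceAlignment:
    """Random ungapped alignment (test helper, not a coalescent sample)."""
    bases = np.array(list("ACGT"))
    seqs = ["".join(bases[rng.integers(0, 4, L)]) for _ in range(n)]
    return SequenceAlignment(ids=[f"s{i}" for i in range(n)], sequences=seqs)
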