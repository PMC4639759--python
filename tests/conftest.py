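import numpy as np
import pytest
from hypothesis import settings

import axokit as ak

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_hetero_genome() -> ak.SimulatedGenome:
    """100 kb repeat-free diploid genome at 1% heterozygosity."""
    return ak.build_genome(
        ak.GenomeSpec(single_copy_length=100_000, heterozygosity=0.01, seed=11)
    )


@pytest.fixture(scope="session")
def repeat_genome() -> ak.SimulatedGenome:
    """500 kb background plus a 50-copy identical 1 kb family (~9% repeat)."""
    fam = ak.RepeatFamilySpec(label="fam50", unit_length=1000, copy_number=50, divergence=0.0)
    return ak.build_genome(
        ak.GenomeSpec(single_copy_length=500_000, repeat_families=(fam,), seed=21)
    )


@pytest.fixture(scope="session")
def homozygous_readset() -> tuple[ak.SimulatedGenome, ak.ReadSet]:
    """300 kb homozygous genome sequenced error-lite at 20x (shared by
    spectrum-fitting tests)."""
    genome = ak.build_genome(ak.GenomeSpec(single_copy_length=300_000, seed=31))
    reads = ak.simulate_reads(
        genome, ak.ReadSimSpec(coverage=20, read_length=100, error_rate=0.002, seed=32)
    )
    return genome, reads


def random_reads(rng: np.random.Generator, n: int, length: int = 100) -> list[str]:
    """Plain random ACGT reads for counter oracle tests."""
    bases = np.array(list("ACGT"))
    return ["".join(bases[rng.integers(0, 4, size=length)]) for _ in range(n)]
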