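import numpy as np
import pytest

from amps import simulate
from amps.methylome import CytosineRecord, GenomeSequence, MethylationCallSet


def random_genome(length: int, seed: int, chrom: str = "chr1",
                  with_n: bool = False) -> GenomeSequence:
    rng = np.random.default_rng(seed)
    alphabet = "ACGTN" if with_n else "ACGT"
    probs = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    seq = "".join(rng.choice(list(alphabet), size=length, p=probs))
    return GenomeSequence(chrom, seq)


@pytest.fixture(scope="session")
def small_bundle():
    """A small generic simulated bundle shared by I/O-level tests."""
    return simulate.make_fixture(
        "annotation_driven", seed=11,
        genome_length=30_000, gene_length=(500, 1500))


@pytest.fixture(scope="session")
def small_calls(small_bundle):
    return small_bundle.calls
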