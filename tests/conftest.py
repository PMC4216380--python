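import numpy as np
import pytest

from seedfam import simulator
from seedfam.read_qc import QualityRead

BASES = "ACGT"


def random_dna(rng, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def tiling_reads(seq: str, read_len: int = 101, step: int = 15) -> list[str]:
    """Error-free reads tiling the sequence with overlap read_len - step."""
    reads = [seq[i : i + read_len] for i in range(0, len(seq) - read_len + 1, step)]
    if (len(seq) - read_len) % step:
        reads.append(seq[-read_len:])
    return reads


def uniform_read(rid: str, seq: str, q: int) -> QualityRead:
    return QualityRead(rid, seq, tuple([q] * len(seq)))


@pytest.fixture
def rng():
    return np.random.default_rng(20140)


@pytest.fixture(scope="session")
def small_family():
    """Five-paralog PawS family with deterministic truth."""
    spec = simulator.FamilySpec(
        n_paralogs=5, mean_divergence=0.08, pawl_fraction=0.0, seed=11
    )
    return simulator.generate_precursor_family(spec)
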