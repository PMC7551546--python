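import numpy as np
import pytest

from mirrorphage.records import AMINO_ACIDS, OrfRecord
from mirrorphage.simulate import SimulationConfig, simulate


def make_orf(contig: str, index: int, sequence: str) -> OrfRecord:
    return OrfRecord(f"{contig}_{index}", contig, index, sequence)


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


@pytest.fixture(scope="session")
def small_dataset():
    """12 genomes, 5 core + 2 accessory families, implanted events."""
    cfg = SimulationConfig(
        n_genomes=12,
        n_core_families=5,
        n_accessory_families=2,
        family_lengths=[120] * 7,
        mean_branch_length=0.05,
        truncation=(0.7, 1.0),
        duplications=((0, 3, 0.05), (2, 7, 0.05)),
        split_gene=(4, (5,), 55, 40),
        seed=11,
    )
    return simulate(cfg)
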