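import numpy as np
import pytest

from arseq.genome import build_genome
from arseq.library import LibraryConfig


@pytest.fixture(scope="session")
def small_genome():
    """50 kbp chromosome + 10 kbp plasmid with one ARS locus."""
    return build_genome(
        [
            {"name": "chr", "length": 50_000, "is_chromosome": True,
             "orfs": [("chr_orf", 20_000, 21_000, "+")]},
            {"name": "pX", "length": 10_000,
             "orfs": [("repX", 2_200, 3_000, "+")],
             "ars_loci": [("ars1", 2_000, 3_200)]},
        ],
        seed=11,
    )


@pytest.fixture(scope="session")
def dup_genome():
    """Plasmid with a byte-identical internal duplication (multi-map model)."""
    return build_genome(
        [
            {"name": "pDup", "length": 30_000,
             "duplications": [(1_000, 5_000, 20_000)]},
            {"name": "chr", "length": 20_000, "is_chromosome": True},
        ],
        seed=7,
    )


@pytest.fixture(scope="session")
def screen_config():
    """Bottleneck sizes scaled down 10x from the screen's 25000/6300/456."""
    return LibraryConfig(n_clones_a=2500, n_clones_b=630, n_clones_c=46, seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
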