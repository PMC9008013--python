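import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from cenfuse.core import NucSequence
from cenfuse.simulate import BlockSpec, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture
def toy_reference(rng):
    return NucSequence("ref", random_seq(rng, 40))


@pytest.fixture
def small_sim_config():
    """Three blocks (inverted/forward/inverted), small monomers, fast to scan."""
    return SimConfig(
        blocks=(
            BlockSpec(4, "-", 0.15),
            BlockSpec(4, "+", 0.0),
            BlockSpec(4, "-", 0.18),
        ),
        monomer_length=120,
        intra_block_divergence=0.02,
        insertion_length_range=(200, 300),
        flank_length=500,
        seed=7,
    )


@pytest.fixture
def donor_configs():
    """Donor chromosomes with mutually well-separated blocks that all stay
    within comfortable scanning distance of the shared ancestral monomer."""
    donor_a = SimConfig(
        blocks=(BlockSpec(4, "+", 0.08), BlockSpec(4, "+", 0.12)),
        monomer_length=150,
        intra_block_divergence=0.02,
        seed=0,
    )
    donor_b = SimConfig(
        blocks=(BlockSpec(4, "-", 0.06), BlockSpec(4, "+", 0.10), BlockSpec(4, "-", 0.14)),
        monomer_length=150,
        intra_block_divergence=0.02,
        seed=0,
    )
    return donor_a, donor_b
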