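import numpy as np
import pytest

from covet import (
    Alignment,
    SimulationSpec,
    build_levels,
    simulate_coupled_alignment,
    toy_structure,
)


@pytest.fixture(scope="session")
def tiny_alignment() -> Alignment:
    """Four hand-written rows with visible conserved/covarying columns."""
    return Alignment(
        sequence_ids=("q", "s1", "s2", "s3"),
        rows=(
            "ACDEFGHIKL",
            "ACDEYGHIKV",
            "ACDWFGHIKV",
            "ACDWYGHIKV",
        ),
        query_id="q",
    )


@pytest.fixture(scope="session")
def small_sim():
    """8-leaf simulated family with two planted coupled pairs."""
    spec = SimulationSpec(
        seed=11,
        n_leaves=8,
        length=12,
        substitution_prob=0.15,
        coupled_pairs=((1, 2), (5, 9)),
        coupling=0.95,
    )
    aln, truth = simulate_coupled_alignment(spec)
    return aln, truth


@pytest.fixture(scope="session")
def small_levels(small_sim):
    aln, _ = small_sim
    return build_levels(aln)


@pytest.fixture(scope="session")
def clustered_structure():
    """20-residue chain with a planted 6-residue spatial cluster."""
    return toy_structure(20, clusters=[({3, 7, 11, 14, 17, 20}, 1.0)], seed=5)


@pytest.fixture(scope="session")
def chain_structure():
    return toy_structure(20, seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
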