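import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_pair(codons_a, codons_b, pair_id="p", species_a="A", species_b="B"):
    """Build a SegmentPair directly from aligned codon triplet lists."""
    from orthotherm.codon_align import SegmentPair, GAP_IDX
    from orthotherm.genetics import codon_index

    idx_a = np.array(
        [GAP_IDX if c == "---" else codon_index(c) for c in codons_a], dtype=np.int16
    )
    idx_b = np.array(
        [GAP_IDX if c == "---" else codon_index(c) for c in codons_b], dtype=np.int16
    )
    return SegmentPair(
        pair_id=pair_id, group_id=None, species_a=species_a, species_b=species_b,
        idx_a=idx_a, idx_b=idx_b, codons_a=list(codons_a), codons_b=list(codons_b),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """100 simulated pairs (60 codons) with indels, as classified SegmentPairs."""
    from orthotherm.simulate import SimulationParams, simulate_pairs
    from orthotherm.codon_align import from_simulated

    params = SimulationParams(
        n_pairs=100, codon_length=60, p_indel=0.05, n_decoys=0, p_misassign=0.0, seed=42
    )
    sim, truth = simulate_pairs(params)
    return [from_simulated(s) for s in sim], truth


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
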