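"""Shared fixtures: hand-built haplotype matrices with known structure."""

import numpy as np
import pytest

from recombscan.io import HaplotypeMatrix


def _hap(n, muts):
    h = np.zeros(n, dtype=np.int16)
    h[list(muts)] = 1
    return h


@pytest.fixture
def splice_matrix():
    """Tree-structured haplotypes plus one known splice.

    Clade {A,B} carries left+right mutations, clade {D,D2} others; C has
    private sites; E/e are ancestral. Row "F" (index 7) is A's left half
    joined to D's right half at SNP 20, so the junction slot is 19.5.
    """
    n = 40
    A = _hap(n, {2, 7, 12, 17})
    B = A.copy()
    C = _hap(n, {5, 25})
    D = _hap(n, {22, 27, 32, 37})
    D2 = D.copy()
    E1 = _hap(n, set())
    E2 = _hap(n, set())
    F = np.concatenate([A[:20], D[20:]])
    return HaplotypeMatrix(
        alleles=np.array([A, B, C, D, D2, E1, E2, F]),
        positions=np.arange(n) * 100.0 + 1000.0,
        sequence_ids=list("ABCDdEeF"),
        snp_ids=[f"s{i}" for i in range(n)],
    )


@pytest.fixture
def tree_matrix():
    """Recombination-free haplotypes from a fixed clade structure."""
    n = 40
    rows = [
        _hap(n, set()),
        _hap(n, set()),
        _hap(n, {2, 12, 22, 32}),
        _hap(n, {2, 12, 22, 32}),
        _hap(n, {2, 12, 22, 32, 5, 15}),
        _hap(n, {7, 17, 27, 37}),
        _hap(n, {7, 17, 27, 37}),
    ]
    return HaplotypeMatrix(
        alleles=np.array(rows),
        positions=np.arange(n) * 50.0 + 500.0,
        sequence_ids=[f"h{i}" for i in range(len(rows))],
        snp_ids=[f"s{i}" for i in range(n)],
    )


@pytest.fixture(scope="session")
def small_sim():
    """One small single-population simulated replicate (fast, seeded)."""
    from recombscan.simulate import SimParams, simulate_dataset

    params = SimParams(
        length=50_000,
        demography="single_pop",
        sample_sizes=(("POP", 30),),
        single_pop_size=8_000,
        recombination="uniform",
        seed=424242,
    )
    return simulate_dataset(params)
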