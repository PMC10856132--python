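"""Shared fixtures: sequences and small synthetic systems."""

import numpy as np
import pytest

from chitosim import (Frame, build_chain, build_fibril, make_sequence,
                      random_solution_frame)


@pytest.fixture(scope="session")
def block_seq():
    """DP 10, DA 50%, block pattern (GGGGGAAAAA)."""
    return make_sequence(10, 0.5, "block")


@pytest.fixture(scope="session")
def alt_seq():
    """DP 10, DA 50%, alternating pattern (GAGAGAGAGA)."""
    return make_sequence(10, 0.5, "alternating")


@pytest.fixture(scope="session")
def single_chain(block_seq):
    return build_chain(block_seq)


@pytest.fixture(scope="session")
def antiparallel_fibril(block_seq):
    """3 sheets x 8 antiparallel chains, zero noise (24-chain system)."""
    return build_fibril(block_seq, 3, 8, "antiparallel")


@pytest.fixture(scope="session")
def parallel_fibril(block_seq):
    return build_fibril(block_seq, 3, 8, "parallel")


@pytest.fixture(scope="session")
def dispersed_frame(block_seq):
    """24 chains placed randomly in the 85 A box, min separation 6 A
    (beyond both the h-bond cutoff and the 4.5 A adjacency cutoff)."""
    return random_solution_frame(block_seq, 24, (85.0, 85.0, 85.0),
                                 min_separation=6.0, seed=42)


def random_no_frame(n_atoms: int, seed: int, box=None, spread=12.0) -> Frame:
    """Random cloud of N/O/H atoms for oracle comparisons."""
    rng = np.random.default_rng(seed)
    elements = rng.choice(["N", "O", "H"], size=n_atoms, p=[0.2, 0.4, 0.4])
    names = np.array([f"{e}{i % 9}" for i, e in enumerate(elements)])
    resnames = rng.choice(["GCS", "NAG"], size=n_atoms)
    resids = rng.integers(1, max(2, n_atoms // 6), size=n_atoms)
    chains = rng.choice(["A", "B", "C"], size=n_atoms)
    coords = rng.uniform(0, spread, size=(n_atoms, 3))
    return Frame(names, resnames, resids, chains, coords,
                 elements=elements, box=box)
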