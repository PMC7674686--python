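"""Shared fixtures: packaged study data and small random-instance builders."""

from __future__ import annotations

import numpy as np
import pytest

from tnfevo import fixtures
from tnfevo.model import SpeciesTree


@pytest.fixture(scope="session")
def species_tree() -> SpeciesTree:
    return fixtures.species_tree()


@pytest.fixture(scope="session")
def count_matrix():
    return fixtures.count_matrix()


@pytest.fixture(scope="session")
def constraints():
    return fixtures.constraints()


def random_species_tree(rng: np.random.Generator, n_leaves: int) -> SpeciesTree:
    """Random rooted binary tree with unit branch lengths and named nodes."""
    parent: dict[str, str | None] = {"N0": None}
    lengths: dict[str, float] = {}
    leaves = ["N0"]
    counter = 1
    while len(leaves) < n_leaves:
        target = leaves.pop(int(rng.integers(0, len(leaves))))
        for _ in range(2):
            name = f"N{counter}"
            counter += 1
            parent[name] = target
            lengths[name] = float(rng.uniform(0.2, 2.0))
            leaves.append(name)
    # rename leaves to species ids for clarity
    mapping = {}
    k = 0
    for node in parent:
        if node not in set(parent.values()):
            mapping[node] = f"sp{k}"
            k += 1
    parent2 = {mapping.get(n, n): (mapping.get(p, p) if p else None) for n, p in parent.items()}
    lengths2 = {mapping.get(n, n): l for n, l in lengths.items()}
    return SpeciesTree(parent2, lengths2)
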