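import numpy as np
import pytest

from multiroot import load_default_structures
from multiroot.tree import SpeciesMapping, random_binary_tree


@pytest.fixture(scope="session")
def structures():
    return load_default_structures()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def mapping():
    return SpeciesMapping.delimiter("_")


def random_mul_tree(rng, species, n_leaves, rooted=False):
    """Random MUL-tree: leaves drawn with replacement from ``species``."""
    counts: dict[str, int] = {}
    labels = []
    for _ in range(n_leaves):
        s = species[int(rng.integers(len(species)))]
        counts[s] = counts.get(s, 0) + 1
        labels.append(f"{s}_{counts[s]}")
    return random_binary_tree(labels, rng, rooted=rooted)
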