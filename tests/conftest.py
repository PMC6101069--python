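import numpy as np
import pytest

from mss.simulate import simulate_star_proteomes, simulate_taxonomy

STAR_DIVERGENCES = {"spA": 0.02, "spB": 0.10, "spC": 0.30}


@pytest.fixture(scope="session")
def chain_tree():
    """Path-graph taxonomy 1 -> 2 -> 3 -> 4 -> 5."""
    from mss.taxonomy import parse_taxdump

    nodes = "\n".join(f"{i}|{max(i - 1, 1)}|no rank" for i in range(1, 6))
    return parse_taxdump(nodes)


@pytest.fixture(scope="session")
def random_tree():
    tree, species = simulate_taxonomy(n_species=12, seed=11)
    return tree, species


@pytest.fixture(scope="session")
def star_fixture():
    """Three species at 2 / 10 / 30 percent divergence from one ancestor."""
    return simulate_star_proteomes(STAR_DIVERGENCES, n_uco=10, seed=5,
                                   length_range=(90, 140))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
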