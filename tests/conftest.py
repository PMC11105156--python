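import numpy as np
import pytest

from refree import CoefficientTable, recenter
from refree.sequence_space import GenotypeSpace
from refree.synthetic import (
    SyntheticSpec,
    fixture_landscapes,
    generate_coefficients,
    sample_classes,
)


@pytest.fixture(scope="session")
def tiny_space():
    """4 states x 2 sites: 16 genotypes, fully enumerable by hand."""
    return GenotypeSpace(tuple("ACDE"), 2)


@pytest.fixture(scope="session")
def small_spec():
    """5 states x 3 sites, pairwise epistasis, all three classes populated."""
    return SyntheticSpec(
        alphabet=tuple("ACDEF"),
        n_sites=3,
        max_order=2,
        beta_sd=(1.0, 0.4),
        sigma_sd=(0.5, 0.2),
        theta_nw=0.5,
        theta_ws=2.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return generate_coefficients(small_spec)


@pytest.fixture(scope="session")
def small_dataset(small_spec, small_truth):
    return sample_classes(small_truth, small_spec)


@pytest.fixture(scope="session")
def landscapes():
    return fixture_landscapes()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_table(alphabet, n_sites, max_order, seed, centered=False):
    """A random coefficient table, optionally recentered."""
    rng = np.random.default_rng(seed)
    table = CoefficientTable.zeros(
        alphabet, n_sites, max_order, theta_nw=0.2, theta_ws=1.2
    )
    for key in table.tables:
        table.tables[key] = np.asarray(
            rng.normal(size=table.tables[key].shape)
        )
    return recenter(table) if centered else table
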