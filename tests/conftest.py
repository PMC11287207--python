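import numpy as np
import pandas as pd
import pytest

from coalmix import CommunityMatrix, SyntheticSpec, generate_experiment


@pytest.fixture
def toy_counts() -> CommunityMatrix:
    """4 samples x 3 taxa with simple integer counts."""
    df = pd.DataFrame(
        [[30, 10, 0], [20, 20, 10], [5, 5, 40], [10, 0, 40]],
        index=["s1", "s2", "s3", "s4"],
        columns=["taxA", "taxB", "taxC"],
    )
    return CommunityMatrix(df, "counts")


@pytest.fixture
def toy_relative(toy_counts) -> CommunityMatrix:
    from coalmix import to_relative

    return to_relative(toy_counts)


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Scaled-down experiment for fast end-to-end tests."""
    return SyntheticSpec(
        n_taxa_river=40, n_taxa_sea=40, n_shared=20,
        n_positive_block=5, n_negative_pairs=2, n_env_sensitive=5,
        sequencing_depth=2000, seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_experiment(small_spec)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition experiment shared across tests."""
    return generate_experiment(SyntheticSpec(seed=5))
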