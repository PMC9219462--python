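import numpy as np
import pandas as pd
import pytest

from fishdiv import CommunityMatrix, ScenarioConfig, assemble_communities


@pytest.fixture
def toy_counts() -> CommunityMatrix:
    data = pd.DataFrame(
        [[1, 0, 3], [2, 3, 0], [0, 1, 1]],
        index=["s1", "s2", "s3"],
        columns=["spA", "spB", "spC"],
    )
    return CommunityMatrix(data, year=2008, kind="count")


@pytest.fixture(scope="session")
def default_bundle():
    """One default-scenario synthetic survey, shared across tests."""
    return assemble_communities(ScenarioConfig(seed=7), with_sequences=False)


def random_community(rng, n_sites=6, n_species=10, occupancy=0.5) -> CommunityMatrix:
    """Random count matrix with every site non-empty."""
    counts = rng.poisson(3.0, size=(n_sites, n_species)) * (
        rng.random((n_sites, n_species)) < occupancy
    )
    for i in range(n_sites):
        if counts[i].sum() == 0:
            counts[i, rng.integers(n_species)] = 1
    return CommunityMatrix(
        pd.DataFrame(
            counts,
            index=[f"site{i}" for i in range(n_sites)],
            columns=[f"sp{j}" for j in range(n_species)],
        )
    )
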