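import numpy as np
import pandas as pd
import pytest

from micrometa.simulate import GeneratorConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic dataset (40 hosts, 300 taxa, three sites), seed 11."""
    return simulate_dataset(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def prov_table(default_sim):
    """Proventriculus-like metacommunity subtable (zero rows dropped)."""
    cols = [c for c in default_sim.counts.columns if c.startswith("proventriculus")]
    tab = default_sim.counts[cols]
    return tab.loc[tab.sum(axis=1) > 0]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_two_block():
    """Two groups of samples with disjoint taxon support (perfect separation)."""
    tab = pd.DataFrame(
        0,
        index=[f"t{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(6)],
    )
    tab.iloc[:3, :3] = [[10, 12, 9], [5, 6, 4], [20, 18, 22]]
    tab.iloc[3:, 3:] = [[8, 11, 10], [15, 14, 13], [3, 2, 4]]
    groups = np.array(["a", "a", "a", "b", "b", "b"])
    return tab, groups
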