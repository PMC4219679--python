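import numpy as np
import pandas as pd
import pytest

from epnet import RatingDataset, SimulationParams, build_catalog, default_domain_specs, simulate_dataset


@pytest.fixture(scope="session")
def catalog():
    return build_catalog()


@pytest.fixture(scope="session")
def specs(catalog):
    return default_domain_specs(catalog)


def make_long(records, catalog=None):
    """records: (community_id, country, urbanicity, observer_id, item_id, response)"""
    frame = pd.DataFrame(
        records,
        columns=["community_id", "country", "urbanicity", "observer_id", "item_id", "response"],
    )
    return RatingDataset(frame, catalog)


@pytest.fixture(scope="session")
def small_dataset():
    """6 communities x 3 observers, full catalog, no degenerate items forced."""
    params = SimulationParams(
        n_communities=6,
        n_observers=3,
        region_mix={("Canada", "urban"): 2, ("Colombia", "rural"): 2, ("India", "urban"): 2},
        seed=7,
    )
    return simulate_dataset(params)


@pytest.fixture(scope="session")
def study_dataset():
    """Default study-design scenario (86 x 3), fixed seed."""
    return simulate_dataset(SimulationParams(seed=11))
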