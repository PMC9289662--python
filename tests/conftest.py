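import numpy as np
import pytest

from parkflux.synthetic_city import (SyntheticCityConfig, fig4_fixture,
                                     generate_city, generate_trajectories)


@pytest.fixture
def fig4():
    return fig4_fixture()


@pytest.fixture
def small_city():
    config = SyntheticCityConfig(
        grid_rows=3, grid_cols=3, tract_side_m=2000.0, n_parks=12,
        n_agents=80, mean_other_activities=3.0, displacement_scale_km=2.0,
        seed=42,
    )
    tracts, parks = generate_city(config)
    trajectories = generate_trajectories(config, tracts)
    return config, tracts, parks, trajectories


def make_city(seed, n_agents=60, n_parks=10, grid=3):
    config = SyntheticCityConfig(
        grid_rows=grid, grid_cols=grid, tract_side_m=2000.0, n_parks=n_parks,
        n_agents=n_agents, mean_other_activities=3.0,
        displacement_scale_km=2.0, seed=seed,
    )
    tracts, parks = generate_city(config)
    trajectories = generate_trajectories(config, tracts)
    return tracts, parks, trajectories
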