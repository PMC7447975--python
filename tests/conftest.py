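"""Shared fixtures: one small synthetic city reused across the suite."""

import numpy as np
import pytest

import cyclesafe.severity as sev
from cyclesafe import synthetic_city as sc


@pytest.fixture(scope="session")
def small_city():
    """16 Voronoi zones on an 8 km x 8 km window with a lattice network."""
    zones, network = sc.generate_city(16, (8000.0, 8000.0), seed=7)
    return zones, network


@pytest.fixture(scope="session")
def surveys_truth(small_city):
    zones, _ = small_city
    return sc.generate_surveys(zones, seed=3)


@pytest.fixture(scope="session")
def path_cache():
    """Shared shortest-path cache so repeated collision draws are cheap."""
    return {}


@pytest.fixture(scope="session")
def default_collisions(small_city, surveys_truth, path_cache):
    """One default-scenario collision table on the small city."""
    zones, network = small_city
    _, truth = surveys_truth
    centers = sc.place_hotspot_centers(zones, network, truth.true_trips,
                                       seed=7, path_cache=path_cache)
    risk = sc.default_risk(zones.window, hotspot_centers=centers)
    table = sc.generate_collisions(zones, network, truth.true_trips, risk,
                                   seed=11, n_events=5000,
                                   population_truth=truth.true_population,
                                   path_cache=path_cache)
    return table, risk


@pytest.fixture(scope="session")
def simple_gamm_spec():
    return sev.ModelSpec(
        linear_terms={"vehicle_type": "automobile"},
        smooth_terms=[sev.SmoothSpec("slope_pct", k=8)],
        spatial_smooth=None,
        random_intercepts=[])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
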