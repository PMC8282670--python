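"""Shared synthetic fixtures: small worlds with known planted effects."""

import numpy as np
import pytest

from cloudshift.grids import FractionGrid, geo_axes
from cloudshift.synthetic_world import (WorldConfig, default_response,
                                        generate_cloud_truth, generate_landcover)
from cloudshift.unmix import run_space_for_time

TRANSITIONS = [("herbaceous", "deciduous_forest"), ("herbaceous", "evergreen_forest")]
PLANTED_DELTA = 0.05


@pytest.fixture(scope="session")
def small_config():
    return WorldConfig(n_lat=60, n_lon=60, seed=7)


@pytest.fixture(scope="session")
def small_world(small_config):
    """(fractions, noiseless clouds, response) on a 60x60 grid."""
    fractions = generate_landcover(small_config)
    response = default_response(noise_sd=0.0)
    clouds = generate_cloud_truth(fractions, response, seed=small_config.seed)
    return fractions, clouds, response


@pytest.fixture(scope="session")
def small_delta_map(small_world):
    fractions, clouds, _ = small_world
    return run_space_for_time(fractions, clouds, TRANSITIONS)


def make_fraction_grid(fractions: np.ndarray, class_names) -> FractionGrid:
    """FractionGrid on a default geographic frame for hand-built arrays."""
    _, n_lat, n_lon = fractions.shape
    lat, lon = geo_axes(n_lat, n_lon, 0.05, 60.0, 10.0)
    return FractionGrid(np.asarray(fractions, dtype=float), tuple(class_names), lat, lon)
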