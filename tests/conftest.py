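"""Shared fixtures: a small deterministic landscape and census.

Everything is generated programmatically at collection time from fixed
seeds; no data files ship with the tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import box

from maupscale import (
    GridSpec,
    default_species_profiles,
    generate_population,
    generate_predictors,
    generate_suitability_mask,
    generate_villages,
    merge_to_coarser,
    voronoi_zonation,
)

FIXTURE_SEED = 20_260_925


@pytest.fixture(scope="session")
def small_spec() -> GridSpec:
    return GridSpec(0.0, 0.0, 0.5, 50, 50)


@pytest.fixture(scope="session")
def small_stack(small_spec):
    stack = generate_predictors(small_spec, n_layers=4, range_km=4.0,
                                seed=FIXTURE_SEED)
    return generate_suitability_mask(stack, 0.25, seed=FIXTURE_SEED + 1)


@pytest.fixture(scope="session")
def small_villages(small_stack):
    villages = generate_villages(small_stack, 120, "uniform",
                                 seed=FIXTURE_SEED + 2)
    for k, profile in enumerate(default_species_profiles(total=100_000)):
        villages = generate_population(villages, small_stack, profile,
                                       seed=FIXTURE_SEED + 3 + k)
    return villages


@pytest.fixture(scope="session")
def small_region(small_spec):
    return box(*small_spec.bounds)


@pytest.fixture(scope="session")
def village_system(small_villages, small_region, small_stack):
    land = float(small_stack.mask.sum()) * small_stack.spec.cell_area()
    return voronoi_zonation(small_villages, small_region, land_area=land)


@pytest.fixture(scope="session")
def subdistrict_system(village_system):
    return merge_to_coarser(village_system, 12, "subdistrict",
                            seed=FIXTURE_SEED + 10)


@pytest.fixture(scope="session")
def district_system(subdistrict_system):
    return merge_to_coarser(subdistrict_system, 4, "district",
                            seed=FIXTURE_SEED + 11)


@pytest.fixture()
def rng():
    return np.random.default_rng(FIXTURE_SEED)
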