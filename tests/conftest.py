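"""Shared fixtures: synthetic bundles at several scales, generated once."""
from __future__ import annotations

import pytest

from nivimyx.clustering import greedy_cluster
from nivimyx.sequences import dedup_ribotypes
from nivimyx.simulate import SimulationConfig, generate_bundle

#: a small, fast bundle used where the study-scale defaults are not needed
SMALL_CONFIG = SimulationConfig(
    seed=7, n_morphospecies=8, n_genera=4, n_soil_only_species=1,
    mean_clusters_per_species=1.5, mean_ribotypes_per_cluster=1.5,
    n_specimens=150, n_samples=16, reads_per_sample_range=(2000, 5000),
    n_unknown_otus=15, n_genus_level_otus=4,
)

#: a clean one-cluster-per-species design for the elevation-shift analysis
SHIFT_CONFIG = SimulationConfig(
    seed=5, n_morphospecies=20, n_genera=5, n_soil_only_species=0,
    mean_clusters_per_species=1.0, mean_ribotypes_per_cluster=1.0,
    optimum_mean=1500.0, optimum_sd=60.0, elevation_breadth=60.0, shift_sd=40.0,
    soil_overlap_fraction=1.0, near_match_fraction=0.0, occupancy_sd=120.0,
    n_specimens=600, n_samples=48, reads_per_sample_range=(3000, 8000),
    n_unknown_otus=10, n_genus_level_otus=0, annotatable_read_fraction=0.7,
)


@pytest.fixture(scope="session")
def default_bundle():
    """The study-scale bundle at the generator's default conditions."""
    return generate_bundle(SimulationConfig())


@pytest.fixture(scope="session")
def small_bundle():
    return generate_bundle(SMALL_CONFIG)


@pytest.fixture(scope="session")
def pool_ribotypes(default_bundle):
    return dedup_ribotypes(default_bundle.pool)


@pytest.fixture(scope="session")
def pool_clusters(pool_ribotypes):
    return greedy_cluster(pool_ribotypes)
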