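"""Shared fixtures: small synthetic cohorts and a cached benchmark run."""

from __future__ import annotations

import numpy as np
import pytest

import brainage as ba


@pytest.fixture(scope="session")
def small_spec() -> ba.CohortSpec:
    return ba.CohortSpec(n_subjects=240, seed=11)


@pytest.fixture(scope="session")
def region_cohort(small_spec) -> ba.Cohort:
    return ba.generate_region_cohort(small_spec)


@pytest.fixture(scope="session")
def two_site_cohorts():
    """Matched region+voxel cohorts for two sites at test scale."""
    return ba.simulate_two_site_study(
        n_site1=400,
        n_site2=120,
        n_voxels=400,
        seed=21,
        voxel_model=ba.VoxelFeatureModel(n_voxels=400, n_latents=50),
    )


@pytest.fixture(scope="session")
def cv_plan() -> ba.CVPlan:
    return ba.CVPlan(k=4, repetitions=2, nested_k=3, c_grid=(2.0**-3, 1.0, 2.0**3), seed=5)


@pytest.fixture(scope="session")
def pca_config() -> ba.PCAConfig:
    return ba.PCAConfig(n_components=25, batch_size=80)


@pytest.fixture(scope="session")
def benchmark_results(two_site_cohorts, cv_plan, pca_config):
    """One fitted benchmark over all eight models, shared across tests."""
    site1, _ = two_site_cohorts
    bench = ba.BrainAgeBenchmark(site1, plan=cv_plan, pca=pca_config)
    return bench.fit()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
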