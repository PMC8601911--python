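"""Shared fixtures: small synthetic landscapes and simulated count datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from grassnet import (
    ABUNDANCE_COVARIATES,
    LandscapeConfig,
    ModelSpec,
    TrueParameters,
    generate_climate,
    generate_landcover,
    simulate_point_counts,
)
from grassnet.covariates import grid_cell_covariates

#: simulation truth used by the recovery and calibration studies: a grassland
#: associate that avoids urban cover, p ≈ 0.5 per 2-min bin, and a density
#: (~20 birds/km² at mean covariates) informative enough that 300 sites give
#: ~180 detections — finite-sample MLE bias is then negligible next to the
#: Monte-Carlo error of the study
RECOVERY_TRUTH = TrueParameters(
    beta_abund={
        "intercept": 3.0,
        "grassland": 0.5,
        "agriculture": 0.1,
        "forest": -0.2,
        "urban": -0.5,
        "tmax": 0.3,
        "prcp": 0.0,
    },
    beta_det=(0.0, -0.3),
)

OFFSET_A = float(np.pi * 0.1**2)


def simulate_dataset(
    seed: int,
    n_sites: int = 300,
    truth: TrueParameters = RECOVERY_TRUTH,
    offset_area_km2: float = OFFSET_A,
):
    """Removal counts at independently drawn standardized covariates."""
    rng = np.random.default_rng(seed)
    cov = pd.DataFrame({c: rng.standard_normal(n_sites) for c in ABUNDANCE_COVARIATES})
    jdate = rng.standard_normal(n_sites)
    sites = pd.DataFrame(
        {
            "site_id": [f"S{i:04d}" for i in range(n_sites)],
            "x": rng.uniform(0, 50_000, n_sites),
            "y": rng.uniform(-50_000, 0, n_sites),
            "jdate": np.full(n_sites, 170),
        }
    )
    return simulate_point_counts(sites, cov, truth, offset_area_km2, jdate, rng=rng)


@pytest.fixture(scope="session")
def small_config() -> LandscapeConfig:
    """20 km × 20 km landscape at 100-m cells: fast but non-trivial."""
    return LandscapeConfig(
        extent=(200, 200),
        fine_cellsize=100.0,
        coarse_cellsize=1000.0,
        class_fractions=(0.40, 0.30, 0.20, 0.10),
        autocorrelation_range=1000.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_landscape(small_config):
    landcover = generate_landcover(small_config)
    climate = generate_climate(small_config)
    return landcover, climate


@pytest.fixture(scope="session")
def small_grid(small_config, small_landscape):
    landcover, climate = small_landscape
    return grid_cell_covariates(landcover, climate, small_config.coarse_cellsize)


@pytest.fixture(scope="session")
def default_spec() -> ModelSpec:
    return ModelSpec()
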