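"""Bundled demonstration study.

A 100 × 100 km synthetic landscape (50-m land-cover cells, 1-km² prediction
grid) with three 196-km² Focal Landscapes each holding three 9-km² GBCAs,
600 removal point-count sites, and two species with known truth:

* ``hotspot`` — a grassland bird whose density tracks maximum temperature,
  which is given a warm bump centered on Focal Landscape 0; its population
  is therefore genuinely concentrated inside that landscape.
* ``uniform`` — a species with no habitat associations at all (intercept-only
  truth and intercept-only fitted model), whose predicted surface is exactly
  flat; no conservation area can hold a significantly elevated density.
"""

from __future__ import annotations

from .config import ClimateParams, LandscapeConfig, TrueParameters
from .pipeline import PipelineConfig, SpeciesConfig


def demo_config(seed: int = 0, n_replicates: int = 1000) -> PipelineConfig:
    """The bundled demo configuration, parameterized only by the seed."""
    landscape = LandscapeConfig(
        extent=(2000, 2000),  # 100 km × 100 km at 50-m cells
        fine_cellsize=50.0,
        coarse_cellsize=1000.0,
        class_fractions=(0.40, 0.30, 0.20, 0.10),
        autocorrelation_range=2000.0,
        climate_params=ClimateParams(),
        seed=seed,
    )
    species = (
        SpeciesConfig(
            name="hotspot",
            true_params=TrueParameters(
                beta_abund={
                    "intercept": 2.5,  # ~12 birds/km² at mean covariates
                    "grassland": 0.4,
                    "forest": -0.3,
                    "urban": -0.4,
                    "tmax": 1.2,
                    "prcp": 0.1,
                },
                beta_det=(0.0, -0.3),  # p = 0.5 per 2-min bin at the mean date
            ),
            # agriculture is the complement of the other three cover classes on
            # a fully labeled 4-class mosaic, so it serves as the reference
            # category; including it would make the design exactly collinear
            abundance_covariates=("grassland", "forest", "urban", "tmax", "prcp"),
        ),
        SpeciesConfig(
            name="uniform",
            true_params=TrueParameters(beta_abund={"intercept": 2.0}),
            abundance_covariates=(),
        ),
    )
    return PipelineConfig(
        landscape=landscape,
        species=species,
        n_sites=600,
        network={
            "n_focal": 3,
            "gbcas_per_focal": 3,
            "focal_area_km2": 196.0,
            "gbca_area_km2": 9.0,
        },
        n_replicates=n_replicates,
        gof_nboot=50,
        hotspot_at_focal=0,
        hotspot_radius_m=8000.0,
        hotspot_amplitude_degc=4.0,
        seed=seed,
    )
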