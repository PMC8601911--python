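"""Configuration objects for the synthetic landscape generator.

The generator emulates the kind of inputs a statewide grassland-bird analysis
consumes: a four-class land-cover mosaic (grassland, agriculture, forest,
urban) with patch structure, smooth climate surfaces (May–July maximum
temperature in °C and total precipitation in mm), a nested network of
priority conservation areas, and removal-protocol point counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

LANDCOVER_CLASSES = ("grassland", "agriculture", "forest", "urban")
#: land-cover classes hostile to grassland birds (drive the suitability mask)
UNSUITABLE_CLASSES = ("forest", "urban")

ABUNDANCE_COVARIATES = (
    "grassland",
    "agriculture",
    "forest",
    "urban",
    "tmax",
    "prcp",
)


@dataclass(frozen=True)
class ClimateParams:
    """Parameters of the two synthetic climate surfaces.

    Trends are total linear changes across the landscape extent (west→east,
    north→south); noise is spatially smoothed and rescaled to the stated
    standard deviation.  ``tmax_hotspot`` optionally adds a Gaussian bump
    ``(x, y, radius_m, amplitude_degC)`` — useful for building species with a
    known density hot spot.
    """

    tmax_mean: float = 28.0  # °C, May–July maximum-temperature normal
    tmax_trend: tuple[float, float] = (2.0, -1.5)  # °C across extent (x, y)
    tmax_noise_sd: float = 0.4
    prcp_mean: float = 320.0  # mm, May–July precipitation total
    prcp_trend: tuple[float, float] = (-40.0, 25.0)  # mm across extent (x, y)
    prcp_noise_sd: float = 12.0
    tmax_hotspot: tuple[float, float, float, float] | None = None


@dataclass(frozen=True)
class LandscapeConfig:
    """Full description of one synthetic landscape.

    ``extent`` is the fine-grid shape (rows, cols); ``class_fractions`` are
    the target areal fractions of (grassland, agriculture, forest, urban) and
    must sum to one; ``autocorrelation_range`` controls patch size in meters.
    """

    extent: tuple[int, int]
    fine_cellsize: float
    coarse_cellsize: float = 1000.0
    class_fractions: tuple[float, float, float, float] = (0.40, 0.30, 0.20, 0.10)
    autocorrelation_range: float = 2000.0
    climate_params: ClimateParams = field(default_factory=ClimateParams)
    seed: int = 0

    def __post_init__(self) -> None:
        nr, nc = self.extent
        if nr <= 0 or nc <= 0:
            raise ConfigurationError("extent must be positive")
        if self.fine_cellsize <= 0:
            raise ConfigurationError("fine_cellsize must be positive")
        fracs = np.asarray(self.class_fractions, dtype=float)
        if fracs.shape != (4,):
            raise ConfigurationError("class_fractions must have four entries")
        if np.any(fracs < 0) or np.any(fracs > 1):
            raise ConfigurationError("class_fractions must lie in [0, 1]")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class_fractions must sum to 1 (got {fracs.sum():.12f})"
            )
        ratio = self.coarse_cellsize / self.fine_cellsize
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigurationError("fine_cellsize must divide coarse_cellsize")

    def fine_geometry(self):
        from .geometry import GridGeometry

        nr, nc = self.extent
        return GridGeometry(nr, nc, self.fine_cellsize)

    def coarse_geometry(self):
        return self.fine_geometry().coarsen(self.coarse_cellsize)


@dataclass(frozen=True)
class TrueParameters:
    """Known simulation truth for one species.

    Abundance uses a log link on density per km² with the named standardized
    covariates; detection uses a logit link on the per-interval (2-min bin)
    detection probability with standardized Julian date.  ``j_intervals`` is
    the number of removal bins (10-min survey → five 2-min bins).
    """

    beta_abund: dict[str, float]  # must include "intercept"
    beta_det: tuple[float, float] = (0.0, 0.0)  # (intercept, jdate)
    j_intervals: int = 5

    def __post_init__(self) -> None:
        if "intercept" not in self.beta_abund:
            raise ConfigurationError("beta_abund must include an 'intercept' entry")
        vals = list(self.beta_abund.values()) + list(self.beta_det)
        if not np.all(np.isfinite(vals)):
            raise ConfigurationError("coefficients must be finite")
        if self.j_intervals < 1:
            raise ConfigurationError("j_intervals must be >= 1")
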