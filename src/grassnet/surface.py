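"""Predicted 1-km² density surfaces.

A surface holds three layers per species: the point prediction exp(xᵀβ̂) and
two error-propagation layers computed by shifting all abundance coefficients
jointly by ±1.96 of their (overdispersion-adjusted) standard errors.  Every
downstream evaluation is run independently on each layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .covariates import GridCovariates, standardize
from .errors import ConfigurationError
from .geometry import GridGeometry
from .removal import FittedModel, predict_expected_density

LAYERS = ("point", "minus", "plus")


@dataclass(frozen=True)
class DensitySurface:
    """Per-cell density (per km²) on the coarse grid, three layers."""

    point: np.ndarray
    minus: np.ndarray
    plus: np.ndarray
    geometry: GridGeometry
    species: str = ""

    def __post_init__(self) -> None:
        for name in LAYERS:
            arr = getattr(self, name)
            if arr.shape != self.geometry.shape:
                raise ConfigurationError(f"layer {name!r} shape does not match grid")
            if not np.all(np.isfinite(arr)) or (arr < 0).any():
                raise ConfigurationError(f"layer {name!r} must be finite and >= 0")

    def layer(self, name: str) -> np.ndarray:
        if name not in LAYERS:
            raise ConfigurationError(f"unknown layer {name!r}; expected one of {LAYERS}")
        return getattr(self, name)

    def statewide_population(self, layer: str = "point") -> float:
        """Total population: Σ cells density × cell area (km²)."""
        cell_area = (self.geometry.cellsize / 1000.0) ** 2
        return float(self.layer(layer).sum() * cell_area)


def predict_surface(
    model: FittedModel,
    grid: GridCovariates,
    species: str = "",
    already_standardized: bool = False,
) -> DensitySurface:
    """Apply a fitted model to every coarse grid cell.

    Grid covariates are standardized with the model's stored scaling
    parameters (the same centering/scaling used at fitting time) unless the
    caller has already done so.
    """
    names = list(model.spec.abundance_covariates)
    table = grid.table
    if names and not already_standardized:
        if model.scaling is None:
            raise ConfigurationError(
                "model carries no scaling parameters; standardize the grid first"
            )
        std, _ = standardize(table[names], model.scaling)
    else:
        std = table[names] if names else table[[]]
    point, minus, plus = predict_expected_density(model, std)
    shape = grid.geometry.shape
    rows = table["row"].to_numpy()
    cols = table["col"].to_numpy()

    def as_grid(vals):
        arr = np.zeros(shape)
        arr[rows, cols] = vals
        return arr

    return DensitySurface(
        point=as_grid(point),
        minus=as_grid(minus),
        plus=as_grid(plus),
        geometry=grid.geometry,
        species=species,
    )


def uniform_surface(geometry: GridGeometry, density: float, species: str = "") -> DensitySurface:
    """Spatially uniform surface — handy for degenerate checks."""
    arr = np.full(geometry.shape, float(density))
    return DensitySurface(
        point=arr, minus=arr.copy(), plus=arr.copy(), geometry=geometry, species=species
    )
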