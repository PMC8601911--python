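"""Covariate extraction and standardization.

Land-cover proportions and climate summaries are computed twice with the same
conventions: in 100-m buffers around survey sites (fitting) and in 1-km² grid
cells (prediction).  Buffer membership is a fine-cell center-in-circle test;
grid-cell summaries are exact block tallies.  Standardization subtracts the
fitting-data mean and divides by the sample (n−1) standard deviation, and the
stored :class:`ScalingParams` are reused verbatim at prediction time so both
stages live on the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ABUNDANCE_COVARIATES, LANDCOVER_CLASSES
from .errors import AlignmentError, ConfigurationError, ExtractionError
from .geometry import GridGeometry


@dataclass(frozen=True)
class ScalingParams:
    """Per-covariate mean and standard deviation from the fitting data.

    ``ddof = 1`` (sample standard deviation) throughout.
    """

    means: pd.Series
    sds: pd.Series
    ddof: int = 1

    def __post_init__(self) -> None:
        if (self.sds <= 0).any():
            bad = list(self.sds.index[self.sds <= 0])
            raise ConfigurationError(f"zero-variance covariate(s): {bad}")


@dataclass(frozen=True)
class GridCovariates:
    """One record per coarse (1-km²) cell: six covariates plus location."""

    table: pd.DataFrame  # columns: row, col, x, y, grassland..prcp
    geometry: GridGeometry

    def layer(self, name: str) -> np.ndarray:
        arr = np.full(self.geometry.shape, np.nan)
        arr[self.table["row"].to_numpy(), self.table["col"].to_numpy()] = self.table[
            name
        ].to_numpy()
        return arr


def site_buffer_covariates(
    sites: pd.DataFrame,
    landcover,
    climate,
    radius_m: float = 100.0,
) -> pd.DataFrame:
    """Covariates in a circular buffer around each site.

    Proportions count fine cells whose centers fall within ``radius_m`` of
    the site; climate covariates are means over the same cells.  Buffers are
    clipped at the raster edge.  Raises :class:`ExtractionError` (naming the
    site) for sites outside the raster extent or with an empty buffer.
    """
    geom: GridGeometry = landcover.geometry
    if climate.geometry != geom:
        raise AlignmentError("land-cover and climate rasters must share a geometry")
    s = geom.cellsize
    reach = int(np.ceil(radius_m / s)) + 1
    out = []
    for rec in sites.itertuples(index=False):
        if not geom.contains_point(rec.x, rec.y):
            raise ExtractionError(f"site {rec.site_id!r} lies outside the raster extent")
        r0, c0 = geom.cell_of(rec.x, rec.y)
        rr = np.arange(max(r0 - reach, 0), min(r0 + reach + 1, geom.nrows))
        cc = np.arange(max(c0 - reach, 0), min(c0 + reach + 1, geom.ncols))
        rows, cols = np.meshgrid(rr, cc, indexing="ij")
        cx, cy = geom.center_of(rows, cols)
        inside = (cx - rec.x) ** 2 + (cy - rec.y) ** 2 <= radius_m**2
        if not inside.any():
            raise ExtractionError(f"site {rec.site_id!r}: empty buffer at radius {radius_m}")
        rows, cols = rows[inside], cols[inside]
        labels = landcover.values[rows, cols]
        n = labels.size
        rec_out = {"site_id": rec.site_id}
        for k, cls in enumerate(LANDCOVER_CLASSES):
            rec_out[cls] = float((labels == k).sum()) / n
        rec_out["tmax"] = float(climate.tmax[rows, cols].mean())
        rec_out["prcp"] = float(climate.prcp[rows, cols].mean())
        out.append(rec_out)
    return pd.DataFrame(out)


def grid_cell_covariates(landcover, climate, coarse_cellsize: float = 1000.0) -> GridCovariates:
    """Exact per-1-km²-cell proportions and climate means via block tallies."""
    geom: GridGeometry = landcover.geometry
    if climate.geometry != geom:
        raise AlignmentError("land-cover and climate rasters must share a geometry")
    try:
        coarse = geom.coarsen(coarse_cellsize)
    except ValueError as exc:
        raise AlignmentError(str(exc)) from exc
    f = int(round(coarse_cellsize / geom.cellsize))

    def block(a: np.ndarray) -> np.ndarray:
        return a.reshape(coarse.nrows, f, coarse.ncols, f).mean(axis=(1, 3))

    layers = {
        cls: block((landcover.values == k).astype(float))
        for k, cls in enumerate(LANDCOVER_CLASSES)
    }
    layers["tmax"] = block(climate.tmax)
    layers["prcp"] = block(climate.prcp)
    rows, cols = np.mgrid[0 : coarse.nrows, 0 : coarse.ncols]
    x, y = coarse.center_of(rows, cols)
    table = pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "x": x.ravel(),
            "y": y.ravel(),
            **{name: arr.ravel() for name, arr in layers.items()},
        }
    )
    return GridCovariates(table=table, geometry=coarse)


def standardize(
    values: pd.DataFrame, params: ScalingParams | None = None
) -> tuple[pd.DataFrame, ScalingParams]:
    """Center and scale covariate columns.

    Fitting mode (``params is None``): compute means and sample SDs from
    ``values`` and return them for reuse.  Prediction mode: reuse the given
    parameters unchanged.
    """
    cols = list(values.columns)
    if params is None:
        means = values.mean()
        sds = values.std(ddof=1)
        params = ScalingParams(means=means, sds=sds)
    else:
        missing = [c for c in cols if c not in params.means.index]
        if missing:
            raise ConfigurationError(f"no scaling parameters for covariate(s) {missing}")
    std = (values - params.means[cols]) / params.sds[cols]
    return std, params


def collinearity_check(covariates: pd.DataFrame, threshold: float = 0.7) -> pd.DataFrame:
    """Pairwise Pearson correlations with a |r| >= threshold flag.

    Mirrors the usual pre-modeling screen for multicollinearity among
    land-cover and climate predictors.
    """
    if len(covariates) < 3:
        raise ConfigurationError("need at least 3 records for a correlation screen")
    sds = covariates.std(ddof=1)
    if (sds == 0).any():
        bad = list(sds.index[sds == 0])
        raise ConfigurationError(f"zero-variance covariate(s): {bad}")
    corr = covariates.corr(method="pearson")
    rows = []
    cols = list(covariates.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = float(corr.loc[a, b])
            rows.append({"var_a": a, "var_b": b, "r": r, "flagged": abs(r) >= threshold})
    return pd.DataFrame(rows)


def abundance_design_matrix(std_covariates: pd.DataFrame, names=ABUNDANCE_COVARIATES):
    """Intercept-first design matrix from standardized covariates."""
    missing = [n for n in names if n not in std_covariates.columns]
    if missing:
        raise ConfigurationError(f"missing covariate column(s) {missing}")
    n = len(std_covariates)
    if len(names) == 0:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), std_covariates[list(names)].to_numpy()])
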