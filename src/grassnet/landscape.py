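"""Synthetic landscapes, conservation networks, survey designs and counts.

Everything downstream of this module (covariate extraction, model fitting,
density surfaces, the spatial null model) is exercised against landscapes
with known ground truth generated here.  All generators are pure functions of
their configuration and a seed: one master seed is split into independent
child streams per generator so modules stay reproducible in isolation.

The observation model follows the removal protocol: a 10-min point count is
divided into J = 5 two-minute bins and only newly detected individuals are
recorded per bin, so an individual present at a site lands in bin j with
probability p(1−p)^{j−1} and is missed entirely with probability (1−p)^J.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import (
    LANDCOVER_CLASSES,
    UNSUITABLE_CLASSES,
    LandscapeConfig,
    TrueParameters,
)
from .conservation import ConservationNetwork, FocalLandscape, Footprint
from .errors import GenerationError, NumericError
from .geometry import GridGeometry
from .removal import RemovalCounts, removal_cell_probs

_STREAMS = {
    "landcover": 0,
    "climate": 1,
    "network": 2,
    "sites": 3,
    "counts": 4,
}


def _child_rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(5)[_STREAMS[stream]])


@dataclass(frozen=True)
class CategoricalRaster:
    """Fine-grid land-cover raster; values index :data:`LANDCOVER_CLASSES`."""

    values: np.ndarray  # uint8, (nrows, ncols)
    geometry: GridGeometry

    def class_proportions(self) -> dict[str, float]:
        n = self.values.size
        return {
            cls: float((self.values == k).sum()) / n
            for k, cls in enumerate(LANDCOVER_CLASSES)
        }


@dataclass(frozen=True)
class ClimateRaster:
    """Fine-grid climate surfaces: maximum temperature (°C), precipitation (mm)."""

    tmax: np.ndarray
    prcp: np.ndarray
    geometry: GridGeometry


def _smooth_unit_field(rng, shape, sigma_cells) -> np.ndarray:
    """Smoothed Gaussian noise rescaled to unit standard deviation."""
    z = rng.standard_normal(shape)
    if sigma_cells > 0:
        z = gaussian_filter(z, sigma=sigma_cells, mode="reflect")
        sd = z.std()
        if sd > 0:
            z = z / sd
    return z


def generate_landcover(config: LandscapeConfig) -> CategoricalRaster:
    """Spatially autocorrelated four-class mosaic with exact class counts.

    Two independent smoothed Gaussian fields are rank-transformed: the first
    splits the landscape into an open (grassland + agriculture) and a closed
    (forest + urban) domain, the second splits each domain into its two
    classes.  Rank thresholds make the realized class counts match the
    configured fractions up to integer rounding, for any seed.
    """
    geom = config.fine_geometry()
    rng = _child_rng(config.seed, "landcover")
    sigma = config.autocorrelation_range / config.fine_cellsize
    u = _smooth_unit_field(rng, geom.shape, sigma)
    v = _smooth_unit_field(rng, geom.shape, sigma)
    fg, fa, ff, fu = config.class_fractions
    n = u.size
    n_g = int(round(fg * n))
    n_a = int(round(fa * n))
    n_f = int(round(ff * n))
    n_open = min(n_g + n_a, n)

    labels = np.empty(n, dtype=np.uint8)
    order_u = np.argsort(u.ravel(), kind="stable")
    open_idx = order_u[:n_open]
    closed_idx = order_u[n_open:]
    # within-domain split by the second field keeps patches two-dimensional
    vflat = v.ravel()
    o = open_idx[np.argsort(vflat[open_idx], kind="stable")]
    labels[o[: min(n_g, o.size)]] = 0  # grassland
    labels[o[min(n_g, o.size) :]] = 1  # agriculture
    c = closed_idx[np.argsort(vflat[closed_idx], kind="stable")]
    labels[c[: min(n_f, c.size)]] = 2  # forest
    labels[c[min(n_f, c.size) :]] = 3  # urban
    return CategoricalRaster(values=labels.reshape(geom.shape), geometry=geom)


def generate_climate(config: LandscapeConfig) -> ClimateRaster:
    """Smooth trend + smoothed-noise climate surfaces on the fine grid."""
    geom = config.fine_geometry()
    rng = _child_rng(config.seed, "climate")
    cp = config.climate_params
    X, Y = geom.cell_centers()
    fx = (X - geom.x0) / geom.width  # 0..1 west→east
    fy = (geom.y0 - Y) / geom.height  # 0..1 north→south
    sigma = config.autocorrelation_range / config.fine_cellsize

    def surface(mean, trend, noise_sd):
        z = mean + trend[0] * (fx - 0.5) + trend[1] * (fy - 0.5)
        if noise_sd > 0:
            z = z + noise_sd * _smooth_unit_field(rng, geom.shape, sigma)
        return z

    tmax = surface(cp.tmax_mean, cp.tmax_trend, cp.tmax_noise_sd)
    if cp.tmax_hotspot is not None:
        hx, hy, radius, amp = cp.tmax_hotspot
        tmax = tmax + amp * np.exp(-((X - hx) ** 2 + (Y - hy) ** 2) / (2 * radius**2))
    prcp = surface(cp.prcp_mean, cp.prcp_trend, cp.prcp_noise_sd)
    return ClimateRaster(tmax=tmax, prcp=prcp, geometry=geom)


def _rectangle_cells(n_cells: int) -> np.ndarray:
    """Near-square block of exactly ``n_cells`` cells anchored at (0, 0)."""
    r = max(int(np.floor(np.sqrt(n_cells))), 1)
    c = n_cells // r
    rows, cols = np.mgrid[0:r, 0:c]
    cells = np.column_stack([rows.ravel(), cols.ravel()])
    rem = n_cells - r * c
    if rem:
        extra = np.column_stack([np.full(rem, r), np.arange(rem)])
        cells = np.vstack([cells, extra])
    return cells


def _coarse_unsuitable_and_grass(config, landcover):
    """Per-coarse-cell unsuitable flag (forest+urban >= 50%) and grass share."""
    geom = landcover.geometry
    coarse = config.coarse_geometry()
    f = int(round(config.coarse_cellsize / config.fine_cellsize))

    def block(a):
        return a.reshape(coarse.nrows, f, coarse.ncols, f).mean(axis=(1, 3))

    unsuit_prop = sum(
        block((landcover.values == LANDCOVER_CLASSES.index(cls)).astype(float))
        for cls in UNSUITABLE_CLASSES
    )
    grass_prop = block((landcover.values == 0).astype(float))
    return unsuit_prop >= 0.5, grass_prop, coarse


def generate_conservation_network(
    config: LandscapeConfig,
    landcover: CategoricalRaster,
    n_focal: int = 3,
    gbcas_per_focal: int = 3,
    focal_area_km2: float = 196.0,
    gbca_area_km2: float = 9.0,
    grass_min: float = 0.30,
    max_unsuitable_frac: float = 0.20,
    max_attempts: int = 100_000,
) -> ConservationNetwork:
    """Place nested Focal Landscape / GBCA footprints in grass-rich regions.

    Focal Landscapes are rectangular cell blocks accepted only where the mean
    grassland proportion is at least ``grass_min`` and at most
    ``max_unsuitable_frac`` of their cells are unsuitable (≥50% forest+urban).
    GBCAs are placed inside their landscape under the same unsuitable-habitat
    cap and must be pairwise disjoint.
    """
    rng = _child_rng(config.seed, "network")
    unsuitable, grass_prop, coarse = _coarse_unsuitable_and_grass(config, landcover)
    cell_km2 = (coarse.cellsize / 1000.0) ** 2

    def place_block(n_cells, region_mask, forbidden, constraint):
        base = _rectangle_cells(n_cells)
        h, w = base[:, 0].max() + 1, base[:, 1].max() + 1
        rr, cc = np.where(region_mask)
        if rr.size == 0:
            raise GenerationError(f"no candidate region for {constraint}")
        for _ in range(max_attempts):
            i = rng.integers(rr.size)
            r0, c0 = rr[i], cc[i]
            cells = base + (r0, c0)
            if cells[:, 0].max() >= coarse.nrows or cells[:, 1].max() >= coarse.ncols:
                continue
            if not region_mask[cells[:, 0], cells[:, 1]].all():
                continue
            if forbidden is not None and forbidden[cells[:, 0], cells[:, 1]].any():
                continue
            if unsuitable[cells[:, 0], cells[:, 1]].mean() > max_unsuitable_frac:
                continue
            if grass_prop[cells[:, 0], cells[:, 1]].mean() < grass_min:
                continue
            return cells
        raise GenerationError(
            f"could not place footprint after {max_attempts} attempts "
            f"(constraint: {constraint})"
        )

    n_focal_cells = int(round(focal_area_km2 / cell_km2))
    n_gbca_cells = int(round(gbca_area_km2 / cell_km2))
    if n_focal_cells < gbcas_per_focal * n_gbca_cells:
        raise GenerationError("GBCAs do not fit inside the requested focal area")
    everywhere = np.ones(coarse.shape, dtype=bool)
    occupied = np.zeros(coarse.shape, dtype=bool)
    landscapes = []
    for i in range(n_focal):
        fcells = place_block(
            n_focal_cells, everywhere, occupied, f"focal landscape {i} placement"
        )
        occupied[fcells[:, 0], fcells[:, 1]] = True
        focal_mask = np.zeros(coarse.shape, dtype=bool)
        focal_mask[fcells[:, 0], fcells[:, 1]] = True
        taken = np.zeros(coarse.shape, dtype=bool)
        gbcas = []
        for j in range(gbcas_per_focal):
            gcells = place_block(
                n_gbca_cells, focal_mask, taken, f"GBCA {j} inside focal landscape {i}"
            )
            taken[gcells[:, 0], gcells[:, 1]] = True
            gbcas.append(Footprint(name=f"FL{i}/GBCA{j}", cells=gcells))
        landscapes.append(
            FocalLandscape(
                footprint=Footprint(name=f"FL{i}", cells=fcells), gbcas=tuple(gbcas)
            )
        )
    return ConservationNetwork(landscapes=tuple(landscapes))


def generate_survey_sites(
    config: LandscapeConfig,
    n_sites: int,
    min_distance_m: float = 400.0,
    season_window: tuple[int, int] = (152, 196),
    max_attempts: int = 100_000,
) -> pd.DataFrame:
    """Survey locations >400 m apart with uniform day-of-year survey dates.

    Rejection sampling with a spatial hash keeps the pairwise-distance check
    O(1) per proposal; placement fails loudly once ``max_attempts`` proposals
    have been exhausted (the landscape cannot pack ``n_sites`` points).
    """
    geom = config.fine_geometry()
    rng = _child_rng(config.seed, "sites")
    # hard packing bound for min-distance points in a rectangle
    bound = int((geom.width + min_distance_m) * (geom.height + min_distance_m)
                / (np.pi / 4 * min_distance_m**2))
    if n_sites > bound:
        raise GenerationError(
            f"{n_sites} sites cannot satisfy {min_distance_m:.0f}-m spacing "
            f"on this extent (packing bound {bound})"
        )
    cell = min_distance_m
    buckets: dict[tuple[int, int], list[tuple[float, float]]] = {}
    xs, ys = [], []
    attempts = 0
    while len(xs) < n_sites:
        if attempts >= max_attempts:
            raise GenerationError(
                f"site spacing infeasible: placed {len(xs)}/{n_sites} after "
                f"{max_attempts} attempts"
            )
        attempts += 1
        x = geom.x0 + rng.uniform(0, geom.width)
        y = geom.y0 - rng.uniform(0, geom.height)
        bx, by = int(x // cell), int(y // cell)
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for px, py in buckets.get((bx + dx, by + dy), ()):
                    if (px - x) ** 2 + (py - y) ** 2 <= min_distance_m**2:
                        ok = False
                        break
        if not ok:
            continue
        buckets.setdefault((bx, by), []).append((x, y))
        xs.append(x)
        ys.append(y)
    jdates = rng.integers(season_window[0], season_window[1] + 1, size=n_sites)
    return pd.DataFrame(
        {
            "site_id": [f"S{i:05d}" for i in range(n_sites)],
            "x": xs,
            "y": ys,
            "jdate": jdates,
        }
    )


def simulate_point_counts(
    sites: pd.DataFrame,
    site_covariates_std: pd.DataFrame,
    params: TrueParameters,
    offset_area_km2: float,
    jdate_std: np.ndarray,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> RemovalCounts:
    """Simulate removal counts from the Poisson-abundance × removal model.

    Per site i: N_i ~ Poisson(λ_i·A) with log λ_i = x_iᵀβ (standardized
    covariates), and each of the N_i individuals is detected in bin j with
    probability p_i(1−p_i)^{j−1} (logit p_i linear in standardized date) or
    never detected with probability (1−p_i)^J.
    """
    if offset_area_km2 <= 0:
        raise NumericError("offset_area_km2 must be positive")
    if rng is None:
        rng = _child_rng(0 if seed is None else seed, "counts")
    names = [k for k in params.beta_abund if k != "intercept"]
    x = np.column_stack(
        [np.ones(len(sites))]
        + [site_covariates_std[n].to_numpy() for n in names]
    )
    beta = np.array([params.beta_abund["intercept"]] + [params.beta_abund[n] for n in names])
    eta = x @ beta
    if not np.all(np.isfinite(eta)):
        raise NumericError("non-finite abundance linear predictor")
    lam = np.exp(eta)
    eta_det = params.beta_det[0] + params.beta_det[1] * np.asarray(jdate_std)
    if not np.all(np.isfinite(eta_det)):
        raise NumericError("non-finite detection linear predictor")
    p = 1.0 / (1.0 + np.exp(-eta_det))
    n_latent = rng.poisson(lam * offset_area_km2)
    pvals = np.atleast_2d(removal_cell_probs(p, params.j_intervals))
    pvals = pvals / pvals.sum(axis=1, keepdims=True)
    cells = rng.multinomial(n_latent, pvals)
    counts = cells[:, : params.j_intervals]
    return RemovalCounts(
        counts=counts,
        covariates=site_covariates_std.reset_index(drop=True),
        jdate=np.asarray(jdate_std, dtype=float),
        coords=sites[["x", "y"]].to_numpy(),
        site_id=sites["site_id"].to_numpy(),
        n_true=n_latent,
    )
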