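"""Constrained random translation–rotation (RTR) spatial null model.

The null model asks: is the mean predicted density inside an existing
conservation area higher than expected for an area of the *same size and
shape* dropped at random into suitable grassland?  Each replicate is the
source footprint rotated by a uniform angle about its centroid, translated
uniformly within the sampling region, and re-rasterized by cell-center
containment.  Replicates covering more than 20% unsuitable habitat (cells
that are ≥50% forest + urban) are discarded and redrawn, mirroring the
average unsuitable share of the real conservation areas.  An area "represents"
a species when its baseline density exceeds the empirical 90th percentile of
1000 replicate means (one-sided top-10% rule).

Three scenarios are supported: Focal Landscapes against statewide
placements, GBCA ensembles (members placed disjointly) against statewide
placements, and GBCA ensembles against placements constrained inside their
own Focal Landscape.  Within a scenario the replicate placements are shared
across species (same geometry, different surfaces), which removes
between-species Monte-Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely import affinity

from .conservation import ConservationNetwork, Footprint, baseline_density
from .covariates import GridCovariates
from .errors import ConfigurationError, PlacementError, ScenarioError
from .geometry import GridGeometry
from .surface import DensitySurface

SCENARIOS = ("focal_vs_state", "gbca_vs_state", "gbca_vs_focal")


@dataclass(frozen=True)
class SuitabilityMask:
    """Boolean coarse grid; True where grassland-bird habitat is suitable."""

    suitable: np.ndarray
    geometry: GridGeometry

    def unsuitable_fraction(self, cells: np.ndarray) -> float:
        return float((~self.suitable[cells[:, 0], cells[:, 1]]).mean())


@dataclass(frozen=True)
class PlacedFootprint:
    """One replicate placement of a source footprint."""

    cells: np.ndarray  # (k, 2) rasterized (row, col)
    source: str
    angle: float  # radians
    translation: tuple[float, float]  # meters
    unsuitable_fraction: float = float("nan")

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]


@dataclass(frozen=True)
class NullDistribution:
    """Replicate mean densities for one species × area × scenario."""

    values: np.ndarray
    species: str = ""
    scenario: str = ""
    area: str = ""
    layer: str = "point"
    n_rejected_unsuitable: int = 0
    n_rejected_geometry: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.size == 0:
            raise ConfigurationError("null distribution must be nonempty")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class RepresentationResult:
    """One-sided top-10% representation verdict for one species × area."""

    species: str
    area: str
    scenario: str
    layer: str
    baseline: float
    null_quantile_value: float
    baseline_quantile: float  # empirical quantile of the baseline in the null
    represented: bool


@dataclass(frozen=True)
class ScenarioResult:
    scenario: str
    layer: str
    results: tuple[RepresentationResult, ...]
    replicate_means: dict  # area -> {species -> np.ndarray of replicate means}

    def representation_counts(self) -> dict[str, int]:
        """Number of represented species per area ('x out of n species')."""
        counts: dict[str, int] = {}
        for r in self.results:
            counts.setdefault(r.area, 0)
            counts[r.area] += int(r.represented)
        return counts


def build_suitability_mask(
    grid: GridCovariates, cell_threshold: float = 0.50
) -> SuitabilityMask:
    """Cells with forest + urban cover at or above the threshold are unsuitable."""
    for name in ("forest", "urban"):
        if name not in grid.table.columns:
            raise ConfigurationError(f"grid covariates lack {name!r}")
    hostile = grid.layer("forest") + grid.layer("urban")
    if np.isnan(hostile).any():
        raise ConfigurationError("grid covariates do not cover every cell")
    return SuitabilityMask(suitable=hostile < cell_threshold, geometry=grid.geometry)


def full_region(geometry: GridGeometry, name: str = "statewide") -> Footprint:
    rows, cols = np.mgrid[0 : geometry.nrows, 0 : geometry.ncols]
    return Footprint(name=name, cells=np.column_stack([rows.ravel(), cols.ravel()]))


class _FootprintSampler:
    """Caches the source polygon so thousands of poses are cheap."""

    def __init__(self, footprint: Footprint, geometry: GridGeometry):
        self.footprint = footprint
        self.geometry = geometry
        self.polygon = footprint.polygon(geometry)
        self.centroid = self.polygon.centroid

    def sample_pose(self, rng: np.random.Generator, region_bbox):
        """One rotated/translated polygon whose bbox fits the region bbox."""
        xmin, ymin, xmax, ymax = region_bbox
        angle = rng.uniform(0, 2 * np.pi)
        rotated = affinity.rotate(
            self.polygon, angle, origin=self.centroid, use_radians=True
        )
        bx0, by0, bx1, by1 = rotated.bounds
        if bx1 - bx0 > xmax - xmin or by1 - by0 > ymax - ymin:
            return None
        dx = rng.uniform(xmin - bx0, xmax - bx1)
        dy = rng.uniform(ymin - by0, ymax - by1)
        return affinity.translate(rotated, dx, dy), angle, (dx, dy)

    def rasterize(self, polygon) -> np.ndarray:
        g = self.geometry
        bx0, by0, bx1, by1 = polygon.bounds
        r0 = max(int(np.floor((g.y0 - by1) / g.cellsize)), 0)
        r1 = min(int(np.floor((g.y0 - by0) / g.cellsize)) + 1, g.nrows)
        c0 = max(int(np.floor((bx0 - g.x0) / g.cellsize)), 0)
        c1 = min(int(np.floor((bx1 - g.x0) / g.cellsize)) + 1, g.ncols)
        if r1 <= r0 or c1 <= c0:
            return np.empty((0, 2), dtype=int)
        rows, cols = np.mgrid[r0:r1, c0:c1]
        rows, cols = rows.ravel(), cols.ravel()
        x, y = g.center_of(rows, cols)
        inside = shapely.contains_xy(polygon, x, y)
        return np.column_stack([rows[inside], cols[inside]])


def _region_bbox(region: Footprint, geometry: GridGeometry):
    r, c = region.cells[:, 0], region.cells[:, 1]
    s = geometry.cellsize
    return (
        geometry.x0 + c.min() * s,
        geometry.y0 - (r.max() + 1) * s,
        geometry.x0 + (c.max() + 1) * s,
        geometry.y0 - r.min() * s,
    )


def _valid_cells(cells, region_mask, n_source, tol) -> bool:
    if cells.shape[0] == 0:
        return False
    if abs(cells.shape[0] - n_source) > tol * n_source:
        return False
    return bool(region_mask[cells[:, 0], cells[:, 1]].all())


def rtr_place_footprint(
    footprint: Footprint,
    region: Footprint,
    geometry: GridGeometry,
    rng: np.random.Generator,
    max_attempts: int = 1000,
    cell_count_tol: float = 0.05,
    mask: SuitabilityMask | None = None,
) -> PlacedFootprint:
    """One shape-preserving random placement of a footprint inside a region.

    Rotation is Uniform(0, 2π) about the footprint centroid; translation is
    uniform over offsets keeping the rotated polygon inside the region
    bounding box.  A pose is accepted when every rasterized cell lies inside
    the region and the cell count stays within ``cell_count_tol`` of the
    source (rasterization tolerance).  The suitability constraint is *not*
    applied here — see :func:`generate_null_distribution`.
    """
    sampler = _FootprintSampler(footprint, geometry)
    region_mask = region.mask(geometry)
    bbox = _region_bbox(region, geometry)
    for _ in range(max_attempts):
        pose = sampler.sample_pose(rng, bbox)
        if pose is None:
            continue
        poly, angle, shift = pose
        cells = sampler.rasterize(poly)
        if _valid_cells(cells, region_mask, footprint.n_cells, cell_count_tol):
            uf = float("nan") if mask is None else mask.unsuitable_fraction(cells)
            return PlacedFootprint(
                cells=cells,
                source=footprint.name,
                angle=angle,
                translation=shift,
                unsuitable_fraction=uf,
            )
    raise PlacementError(
        f"footprint {footprint.name!r} ({footprint.n_cells} cells) could not be "
        f"placed inside region {region.name!r} in {max_attempts} attempts "
        "(size/shape or region-containment constraint)"
    )


def place_ensemble(
    footprints: list[Footprint],
    region: Footprint,
    geometry: GridGeometry,
    rng: np.random.Generator,
    max_attempts: int = 1000,
    cell_count_tol: float = 0.05,
) -> list[PlacedFootprint]:
    """Place ensemble members sequentially, redrawing any overlapping member."""
    total = sum(f.n_cells for f in footprints)
    if total > region.n_cells:
        raise PlacementError(
            f"ensemble of {total} cells exceeds region {region.name!r} "
            f"({region.n_cells} cells)"
        )
    region_mask = region.mask(geometry)
    bbox = _region_bbox(region, geometry)
    occupied = np.zeros(geometry.shape, dtype=bool)
    placed: list[PlacedFootprint] = []
    for fp in footprints:
        sampler = _FootprintSampler(fp, geometry)
        for attempt in range(max_attempts):
            pose = sampler.sample_pose(rng, bbox)
            if pose is None:
                continue
            poly, angle, shift = pose
            cells = sampler.rasterize(poly)
            if not _valid_cells(cells, region_mask, fp.n_cells, cell_count_tol):
                continue
            if occupied[cells[:, 0], cells[:, 1]].any():
                continue
            occupied[cells[:, 0], cells[:, 1]] = True
            placed.append(
                PlacedFootprint(cells=cells, source=fp.name, angle=angle, translation=shift)
            )
            break
        else:
            raise PlacementError(
                f"ensemble member {fp.name!r} could not be placed disjointly in "
                f"{max_attempts} attempts"
            )
    return placed


def _sample_valid_cells(
    sampler: _FootprintSampler,
    region_mask: np.ndarray,
    bbox,
    rng: np.random.Generator,
    max_attempts: int,
    cell_count_tol: float,
    occupied: np.ndarray | None = None,
) -> np.ndarray:
    """One geometry-valid placement from a prebuilt sampler."""
    n_source = sampler.footprint.n_cells
    for _ in range(max_attempts):
        pose = sampler.sample_pose(rng, bbox)
        if pose is None:
            continue
        cells = sampler.rasterize(pose[0])
        if not _valid_cells(cells, region_mask, n_source, cell_count_tol):
            continue
        if occupied is not None and occupied[cells[:, 0], cells[:, 1]].any():
            continue
        return cells
    raise PlacementError(
        f"footprint {sampler.footprint.name!r} ({n_source} cells) could not be "
        f"placed in {max_attempts} attempts (size/shape, region-containment or "
        "overlap constraint)"
    )


def _sample_placements(
    target: Footprint | list[Footprint],
    region: Footprint,
    geometry: GridGeometry,
    mask: SuitabilityMask,
    n: int,
    unsuit_frac: float,
    rng: np.random.Generator,
    max_attempts: int,
    global_cap: int,
    cell_count_tol: float,
):
    """n accepted replicate cell sets plus rejection tallies."""
    is_ensemble = isinstance(target, (list, tuple))
    members = list(target) if is_ensemble else [target]
    samplers = [_FootprintSampler(fp, geometry) for fp in members]
    if is_ensemble and sum(fp.n_cells for fp in members) > region.n_cells:
        raise PlacementError(
            f"ensemble of {sum(fp.n_cells for fp in members)} cells exceeds "
            f"region {region.name!r} ({region.n_cells} cells)"
        )
    region_mask = region.mask(geometry)
    bbox = _region_bbox(region, geometry)
    placements: list[np.ndarray] = []
    n_unsuit = 0
    n_geom = 0
    total_attempts = 0
    while len(placements) < n:
        attempts_this = 0
        while True:
            if total_attempts >= global_cap:
                raise PlacementError(
                    f"global attempt cap {global_cap} reached after "
                    f"{len(placements)} accepted replicates (acceptance rate too low)"
                )
            attempts_this += 1
            total_attempts += 1
            if attempts_this > max_attempts:
                raise PlacementError(
                    f"no acceptable replicate in {max_attempts} attempts "
                    f"(≤{unsuit_frac:.0%} unsuitable-habitat constraint)"
                )
            try:
                if is_ensemble:
                    occupied = np.zeros(geometry.shape, dtype=bool)
                    parts = []
                    for s in samplers:
                        c = _sample_valid_cells(
                            s, region_mask, bbox, rng, max_attempts,
                            cell_count_tol, occupied,
                        )
                        occupied[c[:, 0], c[:, 1]] = True
                        parts.append(c)
                    cells = np.vstack(parts)
                else:
                    cells = _sample_valid_cells(
                        samplers[0], region_mask, bbox, rng, max_attempts,
                        cell_count_tol,
                    )
            except PlacementError:
                n_geom += 1
                continue
            if mask.unsuitable_fraction(cells) > unsuit_frac:
                n_unsuit += 1
                continue
            placements.append(cells)
            break
    return placements, n_unsuit, n_geom


def generate_null_distribution(
    target: Footprint | list[Footprint],
    region: Footprint,
    surface: DensitySurface,
    mask: SuitabilityMask,
    n: int = 1000,
    unsuit_frac: float = 0.20,
    seed: int | None = None,
    layer: str = "point",
    max_attempts: int = 1000,
    global_cap: int = 1_000_000,
    cell_count_tol: float = 0.05,
) -> NullDistribution:
    """Null distribution of replicate mean densities for one target area.

    ``target`` may be a single footprint or a list (a GBCA ensemble, placed
    with pairwise-disjoint members).  Replicates exceeding ``unsuit_frac``
    unsuitable habitat are discarded and redrawn; the rejection tallies are
    reported.  Replicate means use a zero buffer (the 500-m boundary buffer
    applies only to real-area baselines).
    """
    if surface.geometry != mask.geometry:
        raise ConfigurationError("surface and suitability mask grids differ")
    rng = np.random.default_rng(seed)
    placements, n_unsuit, n_geom = _sample_placements(
        target, region, surface.geometry, mask, n, unsuit_frac, rng,
        max_attempts, global_cap, cell_count_tol,
    )
    vals = surface.layer(layer)
    means = np.array([vals[c[:, 0], c[:, 1]].mean() for c in placements])
    name = target.name if isinstance(target, Footprint) else "+".join(f.name for f in target)
    return NullDistribution(
        values=means,
        species=surface.species,
        area=name,
        layer=layer,
        n_rejected_unsuitable=n_unsuit,
        n_rejected_geometry=n_geom,
        seed=seed,
    )


def representation_test(
    baseline: float, null: NullDistribution, quantile: float = 0.90
) -> RepresentationResult:
    """One-sided test: does the baseline fall in the top (1−q) of the null?

    The area is flagged as representing the species when the baseline is
    strictly greater than the empirical ``quantile`` of the replicate means
    (linear-interpolation sample quantile).
    """
    q_val = float(np.quantile(null.values, quantile))
    emp = float(np.mean(null.values < baseline))
    return RepresentationResult(
        species=null.species,
        area=null.area,
        scenario=null.scenario,
        layer=null.layer,
        baseline=float(baseline),
        null_quantile_value=q_val,
        baseline_quantile=emp,
        represented=bool(baseline > q_val),
    )


def run_scenario(
    scenario: str,
    network: ConservationNetwork,
    surfaces: dict[str, DensitySurface],
    mask: SuitabilityMask,
    n_replicates: int = 1000,
    quantile: float = 0.90,
    unsuit_frac: float = 0.20,
    baseline_buffer_m: float = 500.0,
    layer: str = "point",
    seed: int = 0,
    max_attempts: int = 1000,
    global_cap: int = 1_000_000,
    cell_count_tol: float = 0.05,
) -> ScenarioResult:
    """Run one representation scenario for every area × species.

    * ``focal_vs_state``: each Focal Landscape vs statewide placements;
    * ``gbca_vs_state``: each GBCA ensemble (disjoint members) vs statewide;
    * ``gbca_vs_focal``: each GBCA ensemble vs placements inside its own
      Focal Landscape.

    Placements are generated once per area (independent substream of
    ``seed``) and shared across species.
    """
    if scenario not in SCENARIOS:
        raise ScenarioError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if not surfaces:
        raise ScenarioError("no species surfaces given")
    geometry = mask.geometry
    for sp, surf in surfaces.items():
        if surf.geometry != geometry:
            raise ScenarioError(f"surface for {sp!r} is on a different grid")

    statewide = full_region(geometry)
    jobs = []  # (area_name, target, region, baseline_footprint)
    for fl in network.landscapes:
        if scenario == "focal_vs_state":
            jobs.append((fl.name, fl.footprint, statewide, fl.footprint))
        elif scenario == "gbca_vs_state":
            jobs.append((fl.name, list(fl.gbcas), statewide, fl.gbca_ensemble()))
        else:
            jobs.append((fl.name, list(fl.gbcas), fl.footprint, fl.gbca_ensemble()))

    area_seeds = np.random.SeedSequence(seed).spawn(len(jobs))
    results: list[RepresentationResult] = []
    replicate_means: dict[str, dict[str, np.ndarray]] = {}
    for (area_name, target, region, base_fp), ss in zip(jobs, area_seeds):
        rng = np.random.default_rng(ss)
        placements, n_unsuit, n_geom = _sample_placements(
            target, region, geometry, mask, n_replicates, unsuit_frac, rng,
            max_attempts, global_cap, cell_count_tol,
        )
        replicate_means[area_name] = {}
        for sp, surf in surfaces.items():
            vals = surf.layer(layer)
            means = np.array([vals[c[:, 0], c[:, 1]].mean() for c in placements])
            null = NullDistribution(
                values=means,
                species=sp,
                scenario=scenario,
                area=area_name,
                layer=layer,
                n_rejected_unsuitable=n_unsuit,
                n_rejected_geometry=n_geom,
                seed=seed,
            )
            base, _ = baseline_density(surf, base_fp, buffer_m=baseline_buffer_m, layer=layer)
            results.append(representation_test(base, null, quantile))
            replicate_means[area_name][sp] = means
    return ScenarioResult(
        scenario=scenario,
        layer=layer,
        results=tuple(results),
        replicate_means=replicate_means,
    )
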