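"""RTR null model: masks, placements, null distributions, scenarios."""

import numpy as np
import pandas as pd
import pytest

from grassnet.conservation import ConservationNetwork, FocalLandscape, Footprint
from grassnet.covariates import GridCovariates
from grassnet.errors import ConfigurationError, PlacementError, ScenarioError
from grassnet.geometry import GridGeometry
from grassnet.rtr import (
    SuitabilityMask,
    _FootprintSampler,
    build_suitability_mask,
    full_region,
    generate_null_distribution,
    place_ensemble,
    representation_test,
    rtr_place_footprint,
    run_scenario,
)
from grassnet.surface import DensitySurface, uniform_surface

GEOM = GridGeometry(40, 40, 1000.0)


def _square(r0, c0, size, name="sq"):
    rows, cols = np.mgrid[r0 : r0 + size, c0 : c0 + size]
    return Footprint(name=name, cells=np.column_stack([rows.ravel(), cols.ravel()]))


def _all_suitable(geom=GEOM):
    return SuitabilityMask(suitable=np.ones(geom.shape, dtype=bool), geometry=geom)


def _grid_cov(forest, urban, geom=GEOM):
    rows, cols = np.mgrid[0 : geom.nrows, 0 : geom.ncols]
    x, y = geom.center_of(rows, cols)
    n = rows.size
    table = pd.DataFrame(
        {
            "row": rows.ravel(), "col": cols.ravel(),
            "x": x.ravel(), "y": y.ravel(),
            "grassland": np.full(n, 1.0) - forest.ravel() - urban.ravel(),
            "agriculture": np.zeros(n),
            "forest": forest.ravel(), "urban": urban.ravel(),
            "tmax": np.full(n, 28.0), "prcp": np.full(n, 300.0),
        }
    )
    return GridCovariates(table=table, geometry=geom)


class TestSuitabilityMask:
    def test_threshold_rule(self):
        forest = np.zeros(GEOM.shape)
        urban = np.zeros(GEOM.shape)
        forest[0, 0], urban[0, 0] = 0.4, 0.2  # 0.6 >= 0.5 → unsuitable
        forest[0, 1] = 0.49  # below → suitable
        mask = build_suitability_mask(_grid_cov(forest, urban))
        assert not mask.suitable[0, 0]
        assert mask.suitable[0, 1]

    def test_all_grassland_all_suitable(self):
        mask = build_suitability_mask(_grid_cov(np.zeros(GEOM.shape), np.zeros(GEOM.shape)))
        assert mask.suitable.all()


class TestPlacement:
    def test_identity_pose_reproduces_cells(self):
        """Rasterizing the un-transformed polygon returns the source cells."""
        fp = _square(5, 7, 4)
        sampler = _FootprintSampler(fp, GEOM)
        cells = sampler.rasterize(sampler.polygon)
        assert set(map(tuple, cells)) == fp.cell_set()

    def test_quarter_turn_square_preserves_cell_count(self):
        from shapely import affinity

        fp = _square(10, 10, 5)
        sampler = _FootprintSampler(fp, GEOM)
        rotated = affinity.rotate(sampler.polygon, np.pi / 2, origin=sampler.centroid,
                                  use_radians=True)
        assert sampler.rasterize(rotated).shape[0] == fp.n_cells

    def test_random_placements_keep_size_and_region(self):
        fp = _square(0, 0, 6)
        region = full_region(GEOM)
        rng = np.random.default_rng(0)
        for _ in range(50):
            placed = rtr_place_footprint(fp, region, GEOM, rng)
            assert abs(placed.n_cells - fp.n_cells) <= 0.05 * fp.n_cells
            assert (placed.cells >= 0).all()
            assert (placed.cells[:, 0] < GEOM.nrows).all()
            assert (placed.cells[:, 1] < GEOM.ncols).all()

    def test_footprint_larger_than_region_raises(self):
        fp = _square(0, 0, 10)
        region = _square(0, 0, 5, "small")
        with pytest.raises(PlacementError):
            rtr_place_footprint(fp, region, GEOM, np.random.default_rng(1), max_attempts=50)

    def test_ensemble_members_pairwise_disjoint(self):
        members = [_square(0, 0, 3, f"m{i}") for i in range(3)]
        region = full_region(GEOM)
        rng = np.random.default_rng(2)
        for _ in range(20):
            placed = place_ensemble(members, region, GEOM, rng)
            seen = set()
            for p in placed:
                cells = set(map(tuple, p.cells))
                assert not cells & seen
                seen |= cells

    def test_ensemble_exceeding_region_raises(self):
        members = [_square(0, 0, 4, "a"), _square(0, 0, 4, "b")]
        region = _square(0, 0, 5, "tiny")
        with pytest.raises(PlacementError):
            place_ensemble(members, region, GEOM, np.random.default_rng(3), max_attempts=20)


class TestNullDistribution:
    def test_uniform_surface_degenerate_null(self):
        surf = uniform_surface(GEOM, 4.5)
        null = generate_null_distribution(
            _square(0, 0, 5), full_region(GEOM), surf, _all_suitable(), n=50, seed=0
        )
        np.testing.assert_allclose(null.values, 4.5)

    def test_fully_suitable_zero_rejections(self):
        surf = uniform_surface(GEOM, 1.0)
        null = generate_null_distribution(
            _square(0, 0, 5), full_region(GEOM), surf, _all_suitable(),
            n=50, unsuit_frac=0.0, seed=1,
        )
        assert null.n_rejected_unsuitable == 0

    def test_unsuitable_rule_enforced(self):
        # left half unsuitable; replicates must avoid it beyond the 20% slack
        suitable = np.ones(GEOM.shape, dtype=bool)
        suitable[:, :20] = False
        mask = SuitabilityMask(suitable=suitable, geometry=GEOM)
        surf = uniform_surface(GEOM, 1.0)
        rng_seed = 2
        null = generate_null_distribution(
            _square(0, 0, 5), full_region(GEOM), surf, mask, n=100, seed=rng_seed
        )
        assert null.n_rejected_unsuitable > 0

    def test_null_mean_tracks_suitable_spatial_average(self):
        """With one high-density quadrant, the replicate mean approaches the
        suitable-region average of footprint means (Monte-Carlo check)."""
        vals = np.ones(GEOM.shape)
        vals[:20, :20] = 5.0
        surf = DensitySurface(point=vals, minus=vals.copy(), plus=vals.copy(), geometry=GEOM)
        runs = [
            generate_null_distribution(
                _square(0, 0, 4), full_region(GEOM), surf, _all_suitable(),
                n=1000, seed=s,
            ).values
            for s in range(5)
        ]
        grand = np.concatenate(runs)
        # direct spatial average over cells (footprints sample cells nearly
        # uniformly away from edges; 3·SE Monte-Carlo band on the run means)
        expect = vals.mean()
        se = grand.std(ddof=1) / np.sqrt(len(grand))
        assert abs(grand.mean() - expect) <= max(3 * se, 0.15)

    def test_deterministic_given_seed(self):
        surf = uniform_surface(GEOM, 1.0)
        vals = np.random.default_rng(0).uniform(0, 1, GEOM.shape)
        surf = DensitySurface(point=vals, minus=vals.copy(), plus=vals.copy(), geometry=GEOM)
        a = generate_null_distribution(
            _square(0, 0, 5), full_region(GEOM), surf, _all_suitable(), n=30, seed=7
        )
        b = generate_null_distribution(
            _square(0, 0, 5), full_region(GEOM), surf, _all_suitable(), n=30, seed=7
        )
        np.testing.assert_array_equal(a.values, b.values)


class TestRepresentationTest:
    def _null(self, values):
        from grassnet.rtr import NullDistribution

        return NullDistribution(values=np.asarray(values, dtype=float), species="sp",
                                scenario="focal_vs_state", area="A")

    def test_baseline_above_all_replicates_flagged(self):
        null = self._null(np.arange(100))
        res = representation_test(1000.0, null)
        assert res.represented
        assert res.baseline_quantile == 1.0

    def test_baseline_at_median_not_flagged(self):
        null = self._null(np.arange(101))
        res = representation_test(50.0, null)
        assert not res.represented

    def test_degenerate_null_equal_baseline_not_flagged(self):
        null = self._null(np.full(100, 2.0))
        assert not representation_test(2.0, null).represented


def _toy_network():
    fls = []
    for i, (r0, c0) in enumerate([(2, 2), (20, 25)]):
        focal = _square(r0, c0, 8, f"FL{i}")
        gbcas = tuple(
            _square(r0 + 1 + 3 * j, c0 + 1, 2, f"FL{i}/G{j}") for j in range(2)
        )
        fls.append(FocalLandscape(footprint=focal, gbcas=gbcas))
    return ConservationNetwork(landscapes=tuple(fls))


class TestScenarios:
    def test_unknown_scenario_raises(self):
        with pytest.raises(ScenarioError):
            run_scenario("nope", _toy_network(), {"s": uniform_surface(GEOM, 1.0)},
                         _all_suitable())

    def test_uniform_species_never_flagged(self):
        net = _toy_network()
        surfaces = {"flat": uniform_surface(GEOM, 2.0)}
        for scenario in ("focal_vs_state", "gbca_vs_state", "gbca_vs_focal"):
            res = run_scenario(scenario, net, surfaces, _all_suitable(),
                               n_replicates=50, seed=3)
            assert all(not r.represented for r in res.results), scenario

    def test_concentrated_species_flagged_only_where_concentrated(self):
        net = _toy_network()
        vals = np.full(GEOM.shape, 0.1)
        fl0 = net.landscapes[0].footprint
        vals[fl0.cells[:, 0], fl0.cells[:, 1]] = 10.0
        surfaces = {
            "conc": DensitySurface(point=vals, minus=vals.copy(), plus=vals.copy(),
                                   geometry=GEOM)
        }
        res = run_scenario("focal_vs_state", net, surfaces, _all_suitable(),
                           n_replicates=200, seed=4)
        flags = {r.area: r.represented for r in res.results}
        assert flags["FL0"] is True
        assert flags["FL1"] is False

    def test_counts_match_flagged_species(self):
        net = _toy_network()
        surfaces = {"flat": uniform_surface(GEOM, 1.0)}
        res = run_scenario("gbca_vs_focal", net, surfaces, _all_suitable(),
                           n_replicates=30, seed=5)
        counts = res.representation_counts()
        for area, count in counts.items():
            assert count == sum(r.represented for r in res.results if r.area == area)

    def test_mismatched_grids_raise(self):
        other = uniform_surface(GridGeometry(10, 10, 1000.0), 1.0)
        with pytest.raises(ScenarioError):
            run_scenario("focal_vs_state", _toy_network(), {"s": other}, _all_suitable())
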