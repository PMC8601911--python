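"""End-to-end pipeline: simulate → extract → fit → predict → evaluate → randomize.

The pipeline wires the library modules into one seeded, reproducible run.
Every stage draws its randomness from an independent child stream of the
single master seed, so rerunning with a later ``through_stage`` reproduces
the earlier stages bit-for-bit and the whole run is a pure function of
(config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .config import ABUNDANCE_COVARIATES, ClimateParams, LandscapeConfig, TrueParameters
from .conservation import baseline_density, minimum_set, percent_statewide
from .covariates import (
    collinearity_check,
    grid_cell_covariates,
    site_buffer_covariates,
    standardize,
)
from .errors import ConfigurationError
from .landscape import (
    generate_climate,
    generate_conservation_network,
    generate_landcover,
    generate_survey_sites,
    simulate_point_counts,
)
from .removal import (
    ModelSpec,
    auc_holdout,
    crossval_holdout,
    fit,
    gof_parametric_bootstrap,
    overdispersion_adjust,
    spearman_obs_pred,
)
from .rtr import SCENARIOS, build_suitability_mask, run_scenario
from .surface import predict_surface

log = logging.getLogger("grassnet")

STAGES = ("simulate", "extract", "fit", "predict", "evaluate", "randomize")


@dataclass(frozen=True)
class SpeciesConfig:
    """One simulated species: its truth and the model structure fit to it."""

    name: str
    true_params: TrueParameters
    abundance_covariates: tuple[str, ...] = ABUNDANCE_COVARIATES


@dataclass(frozen=True)
class PipelineConfig:
    landscape: LandscapeConfig
    species: tuple[SpeciesConfig, ...]
    n_sites: int = 600
    network: dict = field(default_factory=dict)  # kwargs of generate_conservation_network
    offset_area_km2: float = float(np.pi * 0.1**2)
    j_intervals: int = 5
    buffer_radius_m: float = 100.0
    scenarios: tuple[str, ...] = SCENARIOS
    n_replicates: int = 1000
    quantile: float = 0.90
    targets: tuple[float, float] = (0.20, 0.10)
    gof_nboot: int = 50
    auc_reps: int = 10
    holdout_frac: float = 0.3
    layers: tuple[str, ...] = ("point",)
    baseline_buffer_m: float = 500.0
    unsuit_frac: float = 0.20
    # optional temperature hot spot centered on one focal landscape, to build
    # species with a known density concentration inside that landscape
    hotspot_at_focal: int | None = None
    hotspot_radius_m: float = 8000.0
    hotspot_amplitude_degc: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.species:
            raise ConfigurationError("config must list at least one species")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ConfigurationError("species names must be unique")
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ConfigurationError(f"unknown scenario {s!r}")


@dataclass
class ReportBundle:
    """Everything a pipeline run produced, in memory."""

    config: PipelineConfig
    landcover: object = None
    climate: object = None
    network: object = None
    sites: pd.DataFrame | None = None
    site_covariates: pd.DataFrame | None = None
    scaling: object = None
    collinearity: pd.DataFrame | None = None
    grid_covariates: object = None
    mask: object = None
    counts: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)
    gof: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)
    surfaces: dict = field(default_factory=dict)
    baselines: pd.DataFrame | None = None
    percent_network: pd.DataFrame | None = None
    minimum_sets: pd.DataFrame | None = None
    scenario_results: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def _int_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    through_stage: str = "randomize",
) -> ReportBundle:
    """Execute the configured stages; optionally persist per-stage artifacts.

    ``through_stage`` cuts the run after the named stage; because stage seeds
    are independent child streams of the master seed, a longer rerun
    reproduces every earlier stage exactly.
    """
    if through_stage not in STAGES:
        raise ConfigurationError(f"unknown stage {through_stage!r}")
    last = STAGES.index(through_stage)
    out = None if out_dir is None else gio.ensure_dir(out_dir)
    bundle = ReportBundle(config=config)
    root_ss = np.random.SeedSequence(config.seed)
    ss_counts, ss_gof, ss_valid, ss_scen = root_ss.spawn(4)

    # --- simulate: landscape, network, climate, sites ---
    lcfg = dataclasses.replace(config.landscape, seed=config.seed)
    log.info("simulate: generating land cover (%s cells)", np.prod(lcfg.extent))
    bundle.landcover = generate_landcover(lcfg)
    bundle.network = generate_conservation_network(lcfg, bundle.landcover, **config.network)
    if config.hotspot_at_focal is not None:
        fl = bundle.network.landscapes[config.hotspot_at_focal].footprint
        coarse = lcfg.coarse_geometry()
        cx, cy = coarse.center_of(fl.cells[:, 0].mean(), fl.cells[:, 1].mean())
        cp = dataclasses.replace(
            lcfg.climate_params,
            tmax_hotspot=(float(cx), float(cy), config.hotspot_radius_m,
                          config.hotspot_amplitude_degc),
        )
        lcfg = dataclasses.replace(lcfg, climate_params=cp)
    bundle.climate = generate_climate(lcfg)
    bundle.sites = generate_survey_sites(lcfg, config.n_sites)
    if out:
        gio.write_ascii_grid(out / "landcover.asc", bundle.landcover.values, lcfg.fine_geometry(), fmt="%d")
        gio.write_ascii_grid(out / "tmax.asc", bundle.climate.tmax, lcfg.fine_geometry(), fmt="%.4f")
        gio.write_ascii_grid(out / "prcp.asc", bundle.climate.prcp, lcfg.fine_geometry(), fmt="%.4f")
        gio.network_to_geojson(out / "network.geojson", bundle.network, lcfg.coarse_geometry())
        bundle.sites.to_csv(out / "sites.csv", index=False)
    if last < STAGES.index("extract"):
        return bundle

    # --- extract: covariates at sites and grid cells, suitability mask ---
    raw_site_cov = site_buffer_covariates(
        bundle.sites, bundle.landcover, bundle.climate, radius_m=config.buffer_radius_m
    )
    cov_cols = list(ABUNDANCE_COVARIATES)
    fitting_table = raw_site_cov[cov_cols].copy()
    fitting_table["jdate"] = bundle.sites["jdate"].to_numpy(dtype=float)
    std_table, scaling = standardize(fitting_table)
    bundle.site_covariates = raw_site_cov
    bundle.scaling = scaling
    bundle.collinearity = collinearity_check(fitting_table)
    bundle.grid_covariates = grid_cell_covariates(
        bundle.landcover, bundle.climate, coarse_cellsize=config.landscape.coarse_cellsize
    )
    bundle.mask = build_suitability_mask(bundle.grid_covariates)
    if out:
        raw_site_cov.to_csv(out / "site_covariates.csv", index=False)
        bundle.grid_covariates.table.to_csv(out / "grid_covariates.csv", index=False)
        gio.scaling_to_json(out / "scaling.json", scaling)
        gio.write_mask_ascii(out / "suitability.asc", bundle.mask.suitable, bundle.mask.geometry)
    if last < STAGES.index("fit"):
        return bundle

    # --- fit: simulate counts per species, fit, GOF, validation ---
    species_counts_ss = ss_counts.spawn(len(config.species))
    species_gof_ss = ss_gof.spawn(len(config.species))
    species_valid_ss = ss_valid.spawn(len(config.species))
    for sp, css, gss, vss in zip(
        config.species, species_counts_ss, species_gof_ss, species_valid_ss
    ):
        spec = ModelSpec(
            abundance_covariates=sp.abundance_covariates,
            offset_area_km2=config.offset_area_km2,
            j_intervals=config.j_intervals,
        )
        data = simulate_point_counts(
            bundle.sites,
            std_table,
            sp.true_params,
            config.offset_area_km2,
            std_table["jdate"].to_numpy(),
            rng=np.random.default_rng(css),
        )
        model = fit(data, spec)
        model = dataclasses.replace(model, scaling=scaling)
        log.info("fit %s: converged=%s loglik=%.2f", sp.name, model.converged, model.loglik)
        if config.gof_nboot > 0:
            gof = gof_parametric_bootstrap(model, data, nboot=config.gof_nboot,
                                           seed=_int_seed(gss))
            model = overdispersion_adjust(model, gof.c_hat)
            bundle.gof[sp.name] = gof
        valid: dict = {}
        v1, v2 = np.random.SeedSequence(_int_seed(vss)).spawn(2)
        if config.auc_reps > 0:
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                valid["auc"] = auc_holdout(
                    data, spec, holdout_frac=config.holdout_frac,
                    reps=config.auc_reps, seed=_int_seed(v1),
                )
                valid["crossval"] = crossval_holdout(
                    data, spec, holdout_frac=config.holdout_frac, seed=_int_seed(v2)
                )
                valid["spearman_rho"] = spearman_obs_pred(model, data)
        bundle.counts[sp.name] = data
        bundle.models[sp.name] = model
        bundle.validation[sp.name] = valid
        if out:
            gio.write_counts_csv(out / f"counts_{sp.name}.csv", data.counts, bundle.sites)
            model.summary().to_csv(out / f"model_{sp.name}.csv", index=False)
    if last < STAGES.index("predict"):
        return bundle

    # --- predict: 1-km² density surfaces ---
    for sp in config.species:
        surf = predict_surface(bundle.models[sp.name], bundle.grid_covariates, species=sp.name)
        bundle.surfaces[sp.name] = surf
        if out:
            gio.write_surface_csv(out / f"surface_{sp.name}.csv", surf)
    if last < STAGES.index("evaluate"):
        return bundle

    # --- evaluate: baselines, percent of statewide population, minimum sets ---
    base_rows, pct_rows, ms_rows = [], [], []
    focals = bundle.network.focal_footprints()
    for sp in config.species:
        surf = bundle.surfaces[sp.name]
        for layer in config.layers:
            areas = [(f.name, f) for f in focals] + [
                (fl.name + "/ensemble", fl.gbca_ensemble()) for fl in bundle.network.landscapes
            ]
            for area_name, fp in areas:
                d, ncells = baseline_density(
                    surf, fp, buffer_m=config.baseline_buffer_m, layer=layer
                )
                base_rows.append(
                    {"species": sp.name, "area": area_name, "layer": layer,
                     "mean_density_per_km2": d, "n_cells": ncells}
                )
            base_rows.append(
                {"species": sp.name, "area": "state", "layer": layer,
                 "mean_density_per_km2": float(surf.layer(layer).mean()),
                 "n_cells": int(surf.layer(layer).size)}
            )
            pct = percent_statewide(surf, focals, layer=layer)
            pct_rows.append(
                {"species": sp.name, "layer": layer, "percent_statewide": pct,
                 "meets_20pct_target": pct >= 100 * config.targets[0],
                 "meets_10pct_iucn": pct >= 100 * config.targets[1]}
            )
            for target in config.targets:
                ms = minimum_set(surf, target_frac=target, layer=layer)
                ms_rows.append(
                    {"species": sp.name, "layer": layer, "target": target,
                     "size_km2": ms.size_km2,
                     "achieved_fraction": ms.achieved_fraction}
                )
    bundle.baselines = pd.DataFrame(base_rows)
    bundle.percent_network = pd.DataFrame(pct_rows)
    bundle.minimum_sets = pd.DataFrame(ms_rows)
    if out:
        bundle.baselines.to_csv(out / "baselines.csv", index=False)
        bundle.percent_network.to_csv(out / "percent_statewide.csv", index=False)
        bundle.minimum_sets.to_csv(out / "minimum_sets.csv", index=False)
    if last < STAGES.index("randomize"):
        _write_summary(bundle, out)
        return bundle

    # --- randomize: RTR null-model scenarios ---
    scen_ss = ss_scen.spawn(len(config.scenarios) * len(config.layers))
    k = 0
    rep_rows = []
    for scenario in config.scenarios:
        for layer in config.layers:
            result = run_scenario(
                scenario,
                bundle.network,
                bundle.surfaces,
                bundle.mask,
                n_replicates=config.n_replicates,
                quantile=config.quantile,
                unsuit_frac=config.unsuit_frac,
                baseline_buffer_m=config.baseline_buffer_m,
                layer=layer,
                seed=_int_seed(scen_ss[k]),
            )
            k += 1
            bundle.scenario_results[(scenario, layer)] = result
            counts = result.representation_counts()
            log.info("scenario %s (%s): representation %s", scenario, layer, counts)
            for r in result.results:
                rep_rows.append(dataclasses.asdict(r))
    if rep_rows and out:
        pd.DataFrame(rep_rows).to_csv(out / "representation.csv", index=False)
        for (scenario, layer), result in bundle.scenario_results.items():
            rows = []
            for area, per_sp in result.replicate_means.items():
                df = pd.DataFrame(per_sp)
                df.insert(0, "area", area)
                df.insert(0, "replicate", np.arange(len(df)))
                rows.append(df)
            pd.concat(rows).to_csv(
                out / f"replicate_means_{scenario}_{layer}.csv", index=False
            )
    _write_summary(bundle, out)
    return bundle


def _write_summary(bundle: ReportBundle, out: Path | None):
    summary: dict = {"species": {}, "scenarios": {}}
    for name, model in bundle.models.items():
        entry = {
            "converged": bool(model.converged),
            "c_hat": float(model.c_hat),
            "coefficients": dict(zip(model.spec.param_names(), map(float, model.params))),
        }
        if name in bundle.gof:
            entry["gof_p_value"] = float(bundle.gof[name].p_value)
        valid = bundle.validation.get(name, {})
        if "auc" in valid:
            entry["mean_auc"] = valid["auc"]["mean_auc"]
        if "spearman_rho" in valid:
            rho = valid["spearman_rho"]
            entry["spearman_rho"] = None if np.isnan(rho) else float(rho)
        if "crossval" in valid:
            entry["holdout_rmse"] = valid["crossval"]["rmse"]
        summary["species"][name] = entry
    if bundle.percent_network is not None:
        summary["percent_statewide"] = {
            f"{r.species}/{r.layer}": float(r.percent_statewide)
            for r in bundle.percent_network.itertuples()
        }
    if bundle.minimum_sets is not None:
        summary["minimum_set_km2"] = {
            f"{r.species}/{r.layer}/{r.target:g}": float(r.size_km2)
            for r in bundle.minimum_sets.itertuples()
        }
        if bundle.network is not None:
            summary["network_total_km2"] = float(bundle.network.total_cells)
    for (scenario, layer), result in bundle.scenario_results.items():
        summary["scenarios"][f"{scenario}/{layer}"] = {
            "representation_counts": result.representation_counts(),
            "n_species": len({r.species for r in result.results}),
        }
    bundle.summary = summary
    if out:
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# YAML config loading


def config_from_yaml(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a declarative YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        lc = raw.pop("landscape")
        climate = ClimateParams(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in lc.pop("climate_params", {}).items()
        })
        landscape = LandscapeConfig(
            extent=tuple(lc.pop("extent")),
            climate_params=climate,
            **{k: tuple(v) if isinstance(v, list) else v for k, v in lc.items()},
        )
        species = tuple(
            SpeciesConfig(
                name=s["name"],
                true_params=TrueParameters(
                    beta_abund=dict(s["beta_abund"]),
                    beta_det=tuple(s.get("beta_det", (0.0, 0.0))),
                    j_intervals=int(s.get("j_intervals", 5)),
                ),
                abundance_covariates=tuple(
                    s.get("abundance_covariates", ABUNDANCE_COVARIATES)
                ),
            )
            for s in raw.pop("species")
        )
    except KeyError as exc:
        raise ConfigurationError(f"config is missing required block: {exc}") from exc
    for key in ("scenarios", "layers", "targets"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(landscape=landscape, species=species, **raw)
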