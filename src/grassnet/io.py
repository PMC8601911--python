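"""Readers and writers for the package's on-disk artifacts.

All artifacts are plain text: rasters as ESRI ASCII grids (.asc), footprints
as GeoJSON polygons (plus their cell lists), tables as CSV, configuration
and summaries as YAML/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping

from .conservation import ConservationNetwork, FocalLandscape, Footprint
from .covariates import ScalingParams
from .errors import ConfigurationError
from .geometry import GridGeometry
from .surface import LAYERS, DensitySurface

NODATA = -9999.0


def write_ascii_grid(path, values: np.ndarray, geometry: GridGeometry, fmt: str = "%.10g"):
    """ESRI ASCII grid; the lower-left corner anchors the georeference."""
    header = (
        f"ncols {geometry.ncols}\n"
        f"nrows {geometry.nrows}\n"
        f"xllcorner {geometry.x0:.6f}\n"
        f"yllcorner {geometry.y0 - geometry.height:.6f}\n"
        f"cellsize {geometry.cellsize:.6f}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, values, fmt=fmt)


def read_ascii_grid(path) -> tuple[np.ndarray, GridGeometry]:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cellsize = header["cellsize"]
    geom = GridGeometry(
        nrows,
        ncols,
        cellsize,
        x0=header["xllcorner"],
        y0=header["yllcorner"] + nrows * cellsize,
    )
    return values.reshape(nrows, ncols), geom


def write_surface_csv(path, surface: DensitySurface):
    rows, cols = np.mgrid[0 : surface.geometry.nrows, 0 : surface.geometry.ncols]
    pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "point": surface.point.ravel(),
            "minus": surface.minus.ravel(),
            "plus": surface.plus.ravel(),
        }
    ).to_csv(path, index=False)


def read_surface_csv(path, geometry: GridGeometry, species: str = "") -> DensitySurface:
    df = pd.read_csv(path)
    layers = {}
    for name in LAYERS:
        arr = np.zeros(geometry.shape)
        arr[df["row"], df["col"]] = df[name]
        layers[name] = arr
    return DensitySurface(geometry=geometry, species=species, **layers)


def write_counts_csv(path, counts, sites: pd.DataFrame):
    """Site table with per-interval counts as columns y1..yJ."""
    j = counts.shape[1]
    df = sites.reset_index(drop=True).copy()
    for k in range(j):
        df[f"y{k + 1}"] = counts[:, k]
    df.to_csv(path, index=False)


def read_counts_csv(path) -> tuple[np.ndarray, pd.DataFrame]:
    df = pd.read_csv(path)
    ycols = sorted(
        (c for c in df.columns if c.startswith("y") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if not ycols:
        raise ConfigurationError(f"{path}: no interval-count columns y1..yJ")
    counts = df[ycols].to_numpy(dtype=int)
    return counts, df.drop(columns=ycols)


def network_to_geojson(path, network: ConservationNetwork, geometry: GridGeometry):
    """GeoJSON FeatureCollection with polygons and the source cell lists."""
    features = []

    def feature(fp: Footprint, kind: str, parent: str | None):
        return {
            "type": "Feature",
            "geometry": mapping(fp.polygon(geometry)),
            "properties": {
                "name": fp.name,
                "kind": kind,
                "parent": parent,
                "cells": fp.cells.tolist(),
            },
        }

    for fl in network.landscapes:
        features.append(feature(fl.footprint, "focal_landscape", None))
        for g in fl.gbcas:
            features.append(feature(g, "gbca", fl.name))
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def network_from_geojson(path) -> ConservationNetwork:
    with open(path) as fh:
        gj = json.load(fh)
    focal: dict[str, Footprint] = {}
    gbcas: dict[str, list[Footprint]] = {}
    for feat in gj["features"]:
        props = feat["properties"]
        fp = Footprint(name=props["name"], cells=np.asarray(props["cells"], dtype=int))
        if props["kind"] == "focal_landscape":
            focal[fp.name] = fp
            gbcas.setdefault(fp.name, [])
        else:
            gbcas.setdefault(props["parent"], []).append(fp)
    landscapes = tuple(
        FocalLandscape(footprint=fp, gbcas=tuple(gbcas[name]))
        for name, fp in focal.items()
    )
    return ConservationNetwork(landscapes=landscapes)


def write_mask_ascii(path, mask, geometry: GridGeometry):
    write_ascii_grid(path, mask.astype(int), geometry, fmt="%d")


def scaling_to_json(path, params: ScalingParams):
    with open(path, "w") as fh:
        json.dump(
            {
                "means": params.means.to_dict(),
                "sds": params.sds.to_dict(),
                "ddof": params.ddof,
            },
            fh,
            indent=2,
        )


def scaling_from_json(path) -> ScalingParams:
    with open(path) as fh:
        d = json.load(fh)
    return ScalingParams(
        means=pd.Series(d["means"]), sds=pd.Series(d["sds"]), ddof=d["ddof"]
    )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
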