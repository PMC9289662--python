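"""Readers and writers for the plain-text formats the pipeline exchanges:
GeoJSON (tracts, parks, raw tagged park candidates), trajectory CSV,
MatrixMarket incidence plus id-map CSVs.

Geometry must arrive in a planar metric system.  ``project_lonlat`` offers a
simple local equirectangular projection for small study regions when no
projected dataset is available.
"""
from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from shapely.geometry import mapping, shape

from .exposure import Activity, ExposureNetwork, Trajectory
from .geo_core import GROUP_ORDER, Park, Tract

EARTH_RADIUS_M = 6_371_008.8


def project_lonlat(lon: np.ndarray, lat: np.ndarray,
                   lon0: float, lat0: float) -> tuple[np.ndarray, np.ndarray]:
    """Local equirectangular projection to meters around (lon0, lat0).

    Adequate for city-scale extents (< ~100 km); for anything larger, project
    upstream with a proper CRS and feed planar coordinates in directly.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = np.radians(lon - lon0) * EARTH_RADIUS_M * math.cos(math.radians(lat0))
    y = np.radians(lat - lat0) * EARTH_RADIUS_M
    return x, y


def _load_features(path: str | Path) -> list[dict]:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    return gj["features"]


def read_tracts_geojson(path: str | Path,
                        demographics_csv: Optional[str | Path] = None,
                        id_property: str = "tract_id") -> list[Tract]:
    """Read tract polygons; group counts come from feature properties or are
    joined from a CSV keyed by tract_id."""
    demo = None
    if demographics_csv is not None:
        demo = pd.read_csv(demographics_csv, dtype={id_property: str})
        demo = demo.set_index(id_property)
    tracts = []
    for feat in _load_features(path):
        props = feat.get("properties") or {}
        tid = str(props.get(id_property))
        if tid == "None":
            raise ValueError(f"tract feature missing {id_property!r} property")
        if demo is not None:
            if tid not in demo.index:
                raise ValueError(f"tract {tid!r} missing from demographics table")
            counts = {g: int(demo.loc[tid, g]) for g in GROUP_ORDER if g in demo.columns}
        else:
            counts = {g: int(props[g]) for g in GROUP_ORDER if g in props}
        tracts.append(Tract(tid, shape(feat["geometry"]), counts))
    return tracts


def read_parks_geojson(path: str | Path, id_property: str = "park_id") -> list[Park]:
    parks = []
    for k, feat in enumerate(_load_features(path)):
        props = feat.get("properties") or {}
        pid = str(props.get(id_property, k))
        parks.append(Park(
            pid, shape(feat["geometry"]),
            source_tags=tuple(props.get("source_tags", [])),
            absorbed_ids=tuple(props.get("absorbed_ids", [])),
        ))
    return parks


def read_osm_candidates_geojson(path: str | Path) -> list[dict]:
    """Raw tagged park candidates: features with a ``tags`` property map."""
    records = []
    for k, feat in enumerate(_load_features(path)):
        props = feat.get("properties") or {}
        geom = shape(feat["geometry"]) if feat.get("geometry") else None
        records.append({
            "id": str(props.get("id", k)),
            "tags": props.get("tags") or {},
            "geometry": geom,
        })
    return records


def write_parks_geojson(parks: Sequence[Park], path: str | Path) -> None:
    features = []
    for p in parks:
        features.append({
            "type": "Feature",
            "properties": {
                "park_id": p.park_id,
                "area_km2": p.area_km2,
                "source_tags": list(p.source_tags),
                "absorbed_ids": list(p.absorbed_ids),
            },
            "geometry": mapping(p.region),
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_tracts_geojson(tracts: Sequence[Tract], path: str | Path) -> None:
    features = []
    for t in tracts:
        props = {"tract_id": t.tract_id}
        props.update({g: int(t.group_counts.get(g, 0)) for g in GROUP_ORDER})
        features.append({
            "type": "Feature",
            "properties": props,
            "geometry": mapping(t.region),
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_trajectories_csv(path: str | Path) -> list[Trajectory]:
    """Columns: agent_id, kind in {home, other}, x, y, optional slot.

    Exactly one home row per agent; other rows keep file order (by slot when
    present).
    """
    df = pd.read_csv(path, dtype={"agent_id": str})
    required = {"agent_id", "kind", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory CSV must have columns {sorted(required)}")
    trajectories = []
    for agent_id, g in df.groupby("agent_id", sort=True):
        homes = g[g["kind"] == "home"]
        if len(homes) != 1:
            raise ValueError(f"agent {agent_id!r} has {len(homes)} home rows, expected 1")
        h = homes.iloc[0]
        home = Activity(agent_id, "home", float(h["x"]), float(h["y"]))
        others_df = g[g["kind"] == "other"]
        if "slot" in g.columns and others_df["slot"].notna().all():
            others_df = others_df.sort_values("slot", kind="stable")
        others = tuple(
            Activity(agent_id, "other", float(r["x"]), float(r["y"]),
                     slot=int(r["slot"]) if "slot" in g.columns and pd.notna(r.get("slot")) else None)
            for _, r in others_df.iterrows())
        trajectories.append(Trajectory(agent_id, home, others))
    return trajectories


def write_trajectories_csv(trajectories: Sequence[Trajectory], path: str | Path) -> None:
    rows = []
    for t in trajectories:
        rows.append({"agent_id": t.agent_id, "kind": "home",
                     "x": t.home.x, "y": t.home.y, "slot": ""})
        for a in t.others:
            rows.append({"agent_id": t.agent_id, "kind": "other",
                         "x": a.x, "y": a.y,
                         "slot": a.slot if a.slot is not None else ""})
    pd.DataFrame(rows, columns=["agent_id", "kind", "x", "y", "slot"]).to_csv(
        path, index=False)


def write_network(net: ExposureNetwork, mtx_path: str | Path) -> None:
    """MatrixMarket sparse incidence plus <stem>.tracts.csv / <stem>.parks.csv
    id maps (row/column order)."""
    mtx_path = Path(mtx_path)
    scipy.io.mmwrite(str(mtx_path), net.X.tocoo())
    stem = mtx_path.with_suffix("")
    pd.DataFrame({"row": range(net.n_tracts), "tract_id": net.tract_ids}).to_csv(
        f"{stem}.tracts.csv", index=False)
    pd.DataFrame({"col": range(net.n_parks), "park_id": net.park_ids}).to_csv(
        f"{stem}.parks.csv", index=False)


def read_network(mtx_path: str | Path, radius_m: float = 200.0) -> ExposureNetwork:
    mtx_path = Path(mtx_path)
    X = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    stem = mtx_path.with_suffix("")
    tract_ids = pd.read_csv(f"{stem}.tracts.csv", dtype={"tract_id": str})
    park_ids = pd.read_csv(f"{stem}.parks.csv", dtype={"park_id": str})
    return ExposureNetwork(
        X=X.astype(np.int64),
        tract_ids=tract_ids["tract_id"].tolist(),
        park_ids=park_ids["park_id"].tolist(),
        radius_m=radius_m,
    )
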