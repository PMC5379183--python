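"""Domain types and readers/writers for the tabular and geographic formats
the pipeline touches.

The pipeline consumes two CSV tables:

* events:    ``event_id,user_id,lat,lon,timestamp`` (header required, extra
  columns ignored, timestamp optional and passed through untouched);
* locations: ``location_id,lat,lon``.

Boundary geometry is exported as a GeoJSON FeatureCollection of LineString /
MultiLineString features, one ``scale`` property per feature, lon-lat
coordinate order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import LineString, MultiLineString

from .distance import latlon_to_unit_xyz

logger = logging.getLogger(__name__)

#: A partition is a total mapping location_id -> non-negative community label.
Partition = dict


@dataclass(frozen=True)
class Event:
    """One geotagged observation (photo, check-in, ...) by one user."""

    event_id: str
    user_id: str
    lat: float
    lon: float
    timestamp: str | None = None

    def __post_init__(self):
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")


@dataclass(frozen=True)
class Location:
    """A known point of interest; a Voronoi seed and a graph vertex."""

    location_id: str
    lat: float
    lon: float

    def __post_init__(self):
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")


@dataclass
class RunConfig:
    """Tunable knobs of the full pipeline with the method's defaults:
    100 distance percentiles, vertex degree filter >= 5, best of 100
    community-detection runs, minimum scale-interval size 5."""

    n_percentiles: int = 100
    min_vertex_degree: int = 5
    n_partition_runs: int = 100
    min_interval_size: int = 5
    random_seed: int = 0
    weighted_percentiles: bool = False  # replicate edges by movement weight
    smoothing_max_sweeps: int = 100

    def __post_init__(self):
        for name in ("n_percentiles", "n_partition_runs", "smoothing_max_sweeps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.min_interval_size < 1:
            raise ValueError("min_interval_size must be >= 1")
        if self.min_vertex_degree < 0:
            raise ValueError("min_vertex_degree must be >= 0")


def normalize_labels(partition: Mapping) -> Partition:
    """Renumber community labels to 0..k-1 by first appearance over the
    sorted domain. Community labels are arbitrary; this gives a canonical
    representative for serialization and comparison."""
    out = {}
    remap = {}
    for loc in sorted(partition):
        lab = partition[loc]
        if lab not in remap:
            remap[lab] = len(remap)
        out[loc] = remap[lab]
    return out


# ---------------------------------------------------------------------------
# CSV readers
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = ("event_id", "user_id", "lat", "lon")


def read_events(path, column_map: Mapping[str, str] | None = None) -> list[Event]:
    """Read an events CSV.

    ``column_map`` optionally maps the canonical names (``event_id``,
    ``user_id``, ``lat``, ``lon``, ``timestamp``) to the file's column names.
    Duplicate event ids are collapsed to the first occurrence; rows with
    unparseable or out-of-range coordinates are dropped and counted in the
    log. An empty file yields an empty list with a warning.
    """
    cmap = {c: c for c in (*_EVENT_COLUMNS, "timestamp")}
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, dtype={cmap["event_id"]: str, cmap["user_id"]: str})
    missing = [c for c in _EVENT_COLUMNS if cmap[c] not in df.columns]
    if missing:
        raise ValueError(f"events file {path} missing required columns: {missing}")
    has_ts = cmap["timestamp"] in df.columns

    n_raw = len(df)
    if n_raw == 0:
        logger.warning("events file %s is empty", path)
        return []

    lat = pd.to_numeric(df[cmap["lat"]], errors="coerce")
    lon = pd.to_numeric(df[cmap["lon"]], errors="coerce")
    ok = (
        lat.between(-90, 90)
        & lon.between(-180, 180)
        & df[cmap["event_id"]].notna()
        & df[cmap["user_id"]].notna()
    )
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("dropped %d malformed event rows from %s", n_bad, path)
    df = df[ok]
    n_before = len(df)
    df = df.drop_duplicates(subset=cmap["event_id"], keep="first")
    if len(df) < n_before:
        logger.info("collapsed %d duplicate event_ids in %s", n_before - len(df), path)

    events = []
    for row in df.itertuples(index=False):
        r = dict(zip(df.columns, row))
        events.append(
            Event(
                event_id=str(r[cmap["event_id"]]),
                user_id=str(r[cmap["user_id"]]),
                lat=float(r[cmap["lat"]]),
                lon=float(r[cmap["lon"]]),
                timestamp=str(r[cmap["timestamp"]]) if has_ts and pd.notna(r[cmap["timestamp"]]) else None,
            )
        )
    return events


def read_locations(path) -> list[Location]:
    """Read a locations CSV with columns ``location_id,lat,lon``."""
    df = pd.read_csv(path, dtype={"location_id": str})
    missing = [c for c in ("location_id", "lat", "lon") if c not in df.columns]
    if missing:
        raise ValueError(f"locations file {path} missing required columns: {missing}")
    if df["location_id"].duplicated().any():
        raise ValueError(f"locations file {path} has duplicate location_ids")
    return [
        Location(str(r.location_id), float(r.lat), float(r.lon))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Event -> location assignment
# ---------------------------------------------------------------------------

def assign_events_to_locations(
    events: Sequence[Event], locations: Sequence[Location]
) -> list[tuple[str, str, str]]:
    """Associate each event with the closest known location (great-circle
    distance); ties break to the lexicographically smallest location_id.

    Returns one ``(event_id, user_id, location_id)`` triple per event.
    The result is independent of the ordering of ``locations``.
    """
    if not locations:
        raise ValueError("locations must be non-empty")
    locs = sorted(locations, key=lambda l: l.location_id)
    xyz = latlon_to_unit_xyz([l.lat for l in locs], [l.lon for l in locs])
    tree = cKDTree(xyz)
    if not events:
        return []
    exyz = latlon_to_unit_xyz([e.lat for e in events], [e.lon for e in events])
    k = min(len(locs), 4)
    dist, idx = tree.query(exyz, k=k)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    out = []
    for i, ev in enumerate(events):
        d0 = dist[i, 0]
        # candidates numerically tied with the nearest; break by id
        tied = [idx[i, j] for j in range(k) if dist[i, j] <= d0 + 1e-12]
        best = min(tied, key=lambda j: locs[j].location_id)
        out.append((ev.event_id, ev.user_id, locs[best].location_id))
    return out


# ---------------------------------------------------------------------------
# GeoJSON boundaries
# ---------------------------------------------------------------------------

def write_boundaries_geojson(segments: Iterable[tuple[int, LineString | MultiLineString]], path) -> None:
    """Write ``(scale, geometry)`` pairs as a GeoJSON FeatureCollection.

    Geometries are LineString or MultiLineString in lon-lat order; each
    feature carries a single ``scale`` integer property.
    """
    features = []
    for scale, geom in segments:
        if isinstance(geom, LineString):
            geometry = {"type": "LineString", "coordinates": [list(c) for c in geom.coords]}
        elif isinstance(geom, MultiLineString):
            geometry = {
                "type": "MultiLineString",
                "coordinates": [[list(c) for c in line.coords] for line in geom.geoms],
            }
        else:
            raise TypeError(f"unsupported boundary geometry: {geom.geom_type}")
        features.append(
            {"type": "Feature", "geometry": geometry, "properties": {"scale": int(scale)}}
        )
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_boundaries_geojson(path) -> list[tuple[int, LineString | MultiLineString]]:
    """Inverse of :func:`write_boundaries_geojson`."""
    with open(path) as fh:
        doc = json.load(fh)
    out = []
    for feat in doc["features"]:
        geom = feat["geometry"]
        if geom["type"] == "LineString":
            g = LineString([tuple(c) for c in geom["coordinates"]])
        elif geom["type"] == "MultiLineString":
            g = MultiLineString([[tuple(c) for c in part] for part in geom["coordinates"]])
        else:
            raise ValueError(f"unsupported geometry type {geom['type']}")
        out.append((int(feat["properties"]["scale"]), g))
    return out


def write_partition_csv(partition: Mapping, path) -> None:
    pd.DataFrame(
        {"location_id": sorted(partition), "community": [partition[k] for k in sorted(partition)]}
    ).to_csv(path, index=False)


def read_partition_csv(path) -> Partition:
    df = pd.read_csv(path, dtype={"location_id": str})
    return dict(zip(df["location_id"], df["community"].astype(int)))
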