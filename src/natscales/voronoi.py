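"""Voronoi tessellation of the region, neighbourhood smoothing and
boundary geometry.

Locations seed a planar Voronoi diagram (computed directly in lon-lat:
only the cell topology matters to smoothing, and topology is invariant to
the mild anisotropy of unprojected coordinates at regional extents). Two
cells are neighbours when they share a boundary edge of positive length —
point contact does not count.

Smoothing removes spatial noise from network-derived partitions: in
synchronous sweeps, a cell adopts a competing value when that value holds
a strict majority (> 1/2) of its closed neighbourhood (the cell plus its
neighbours). The same rule applied to whole tuples of per-scale labels
aligns boundaries across scales (multi-scale smoothing). Boundaries are
the shared Voronoi edges whose two cells carry different labels.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
from shapely import voronoi_polygons
from shapely.geometry import GeometryCollection, LineString, MultiLineString, MultiPoint, Point, box
from shapely.strtree import STRtree

from .io import Location, Partition

#: shared edges shorter than this (degrees) are treated as point contact
_MIN_SHARED_EDGE = 1e-9


@dataclass
class Tessellation:
    """Clipped Voronoi cells over the location seeds.

    ``adjacency`` is symmetric and irreflexive; ``shared_edges`` caches the
    geometry of each shared cell boundary, keyed by the sorted id pair.
    """

    seeds: list
    cells: dict
    adjacency: dict
    shared_edges: dict = field(default_factory=dict)

    @property
    def domain(self) -> set:
        return set(self.cells)


def _collinear(points: np.ndarray) -> bool:
    if len(points) < 3:
        return True
    p0 = points[0]
    d = points - p0
    cross = d[:, 0, None] * d[None, :, 1] - d[:, 1, None] * d[None, :, 0]
    return bool(np.allclose(cross, 0.0))


def build_tessellation(locations: Sequence[Location], clip_region=None) -> Tessellation:
    """Voronoi tessellation of the seeds, clipped to ``clip_region``
    (default: the seed bounding box padded by 5% per side).

    Requires at least 3 non-collinear, distinct seeds. Adjacency links
    cells sharing an edge of positive length.
    """
    pts = np.array([[l.lon, l.lat] for l in locations], dtype=float)
    if len(locations) < 3 or _collinear(pts):
        raise ValueError("tessellation requires >= 3 non-collinear seeds")
    if len(np.unique(pts, axis=0)) != len(pts):
        raise ValueError("duplicate seed coordinates")

    if clip_region is None:
        minx, miny = pts.min(axis=0)
        maxx, maxy = pts.max(axis=0)
        padx = 0.05 * (maxx - minx)
        pady = 0.05 * (maxy - miny)
        clip_region = box(minx - padx, miny - pady, maxx + padx, maxy + pady)

    raw = voronoi_polygons(MultiPoint(pts), extend_to=clip_region)
    polys = [g.intersection(clip_region) for g in raw.geoms]

    # match each polygon back to the seed it contains
    seed_points = [Point(xy) for xy in pts]
    tree = STRtree(seed_points)
    cells = {}
    for poly in polys:
        if poly.is_empty:
            continue
        hits = [i for i in tree.query(poly) if poly.covers(seed_points[i])]
        if len(hits) != 1:  # pragma: no cover - voronoi_polygons guarantees this
            raise RuntimeError(f"cell matched {len(hits)} seeds")
        cells[locations[hits[0]].location_id] = poly
    if len(cells) != len(locations):
        raise RuntimeError("some seeds received no Voronoi cell")

    ids = sorted(cells)
    cell_geoms = [cells[i] for i in ids]
    cell_tree = STRtree(cell_geoms)
    adjacency = {i: set() for i in ids}
    shared_edges = {}
    for a_idx, a_id in enumerate(ids):
        for b_idx in cell_tree.query(cell_geoms[a_idx]):
            b_idx = int(b_idx)
            if b_idx <= a_idx:
                continue
            inter = cell_geoms[a_idx].intersection(cell_geoms[b_idx])
            if inter.is_empty or inter.length <= _MIN_SHARED_EDGE:
                continue
            lines = _as_lines(inter)
            if lines is None:
                continue
            b_id = ids[b_idx]
            adjacency[a_id].add(b_id)
            adjacency[b_id].add(a_id)
            shared_edges[(a_id, b_id)] = lines
    return Tessellation(list(locations), cells, adjacency, shared_edges)


def _as_lines(geom):
    """Extract the 1-D part of an intersection geometry, or None."""
    if isinstance(geom, LineString):
        return geom
    if isinstance(geom, MultiLineString):
        return geom
    if isinstance(geom, GeometryCollection):
        lines = [g for g in geom.geoms if isinstance(g, (LineString, MultiLineString))]
        if not lines:
            return None
        flat = []
        for g in lines:
            flat.extend(g.geoms if isinstance(g, MultiLineString) else [g])
        return flat[0] if len(flat) == 1 else MultiLineString(flat)
    return None


def _adjacency_of(tess_or_adjacency) -> Mapping:
    if isinstance(tess_or_adjacency, Tessellation):
        return tess_or_adjacency.adjacency
    return tess_or_adjacency


def _majority_sweeps(values: dict, adjacency: Mapping, max_sweeps: int) -> dict:
    """Synchronous strict-closed-neighbourhood-majority sweeps over generic
    hashable values; stops at a fixed point, on a detected 2-cycle (returning
    the first repeated state) or after ``max_sweeps``."""
    state = dict(values)
    prev = None
    for _ in range(max_sweeps):
        nxt = {}
        changed = False
        for cell, current in state.items():
            neigh = adjacency.get(cell, ())
            counts = Counter(state[n] for n in neigh)
            counts[current] += 1
            size = len(neigh) + 1
            value, count = counts.most_common(1)[0]
            if value != current and 2 * count > size:
                nxt[cell] = value
                changed = True
            else:
                nxt[cell] = current
        if not changed:
            return state
        if prev is not None and nxt == prev:  # 2-cycle: keep first repeated state
            return nxt
        prev, state = state, nxt
    return state


def smooth_partition(partition: Mapping, tess, max_sweeps: int = 100) -> Partition:
    """Majority-smooth a partition on the tessellation.

    A cell flips to a different community only when that community holds a
    strict majority of the cell's closed neighbourhood; a plurality short
    of a majority never triggers a flip, so no new label can appear.
    The partition must cover every tessellation seed; the returned
    partition covers exactly the tessellation domain.
    """
    adjacency = _adjacency_of(tess)
    missing = set(adjacency) - set(partition)
    if missing:
        raise ValueError(f"partition missing tessellation seeds: {sorted(missing)[:5]}")
    values = {cell: partition[cell] for cell in adjacency}
    return _majority_sweeps(values, adjacency, max_sweeps)


def smooth_multiscale(partitions: Sequence[Mapping], tess, max_sweeps: int = 100) -> list[Partition]:
    """Joint smoothing over several scales: each cell carries the tuple of
    its per-scale labels (smallest scale first) and the majority rule acts
    on entire tuples compared by equality. Returns the per-scale
    projections of the final tuples."""
    adjacency = _adjacency_of(tess)
    if not partitions:
        raise ValueError("need at least one partition")
    domain = set(adjacency)
    for i, part in enumerate(partitions):
        if not domain <= set(part):
            raise ValueError(f"partition {i} does not cover the tessellation domain")
    values = {cell: tuple(part[cell] for part in partitions) for cell in domain}
    final = _majority_sweeps(values, adjacency, max_sweeps)
    return [{cell: tup[i] for cell, tup in final.items()} for i in range(len(partitions))]


def extract_boundaries(tess: Tessellation, partition: Mapping) -> list:
    """Shared Voronoi edges separating cells with different labels, as
    shapely lines in lon-lat. Determined by (adjacency, labels) alone and
    invariant to label renumbering."""
    missing = tess.domain - set(partition)
    if missing:
        raise ValueError(f"partition missing tessellation seeds: {sorted(missing)[:5]}")
    out = []
    for (a, b), geom in sorted(tess.shared_edges.items()):
        if partition[a] != partition[b]:
            out.append(geom)
    return out
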