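"""User co-occurrence movement graphs and their distance-percentile family.

The movement graph G = (V, E) has known locations as vertices; an edge
joins two locations whenever at least one user produced events at both,
weighted by the number of distinct such users. Each edge carries the
great-circle distance between its endpoints. The graph is undirected,
without self-loops.

Sorting edge distances and cutting at the s-th percentile threshold m_s
yields the nested family of percentile graphs G_s (s = 1..100): G_s keeps
every vertex but only the edges with d(e) <= m_s, so G_s ⊆ G_s' for
s <= s' and G_100 = G.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .distance import haversine_km
from .io import Location

#: MovementGraph — a networkx.Graph whose nodes are location_ids and whose
#: edges carry ``weight`` (distinct shared users) and ``distance_km``.
MovementGraph = nx.Graph


@dataclass(frozen=True)
class PercentileThresholds:
    """Nearest-rank percentile thresholds m_1..m_n of the edge-distance
    distribution (km). Non-decreasing; m_n is the maximum edge distance."""

    m: tuple

    def __post_init__(self):
        if any(b < a for a, b in zip(self.m, self.m[1:])):
            raise ValueError("percentile thresholds must be non-decreasing")

    def __len__(self):
        return len(self.m)

    def __getitem__(self, s: int) -> float:
        """Threshold for percentile s (1-based)."""
        if not 1 <= s <= len(self.m):
            raise ValueError(f"percentile {s} out of range 1..{len(self.m)}")
        return self.m[s - 1]


def build_cooccurrence_graph(
    assignments: Iterable[tuple[str, str]],
    locations: Sequence[Location] | Mapping[str, Location],
) -> MovementGraph:
    """Build the weighted co-occurrence graph from (user_id, location_id)
    assignment pairs.

    For each unordered location pair the weight is the number of distinct
    users with at least one event at both endpoints; zero-weight pairs are
    absent. Every location with at least one assignment becomes a vertex
    (isolated ones included). Repeated visits by the same user to the same
    pair count once.
    """
    if not isinstance(locations, Mapping):
        locations = {l.location_id: l for l in locations}

    by_user: dict[str, set] = {}
    seen_locations = set()
    for user_id, loc_id in assignments:
        if loc_id not in locations:
            raise ValueError(f"assignment references unknown location_id {loc_id!r}")
        by_user.setdefault(user_id, set()).add(loc_id)
        seen_locations.add(loc_id)

    g = nx.Graph()
    g.add_nodes_from(seen_locations)
    for visited in by_user.values():
        for u, v in itertools.combinations(sorted(visited), 2):
            if g.has_edge(u, v):
                g[u][v]["weight"] += 1
            else:
                g.add_edge(u, v, weight=1)
    for u, v, data in g.edges(data=True):
        lu, lv = locations[u], locations[v]
        data["distance_km"] = haversine_km(lu.lat, lu.lon, lv.lat, lv.lon)
    for n in g.nodes:
        g.nodes[n]["lat"] = locations[n].lat
        g.nodes[n]["lon"] = locations[n].lon
    return g


def prune_low_degree(graph: MovementGraph, min_degree: int) -> MovementGraph:
    """Drop vertices whose unweighted degree is below ``min_degree``,
    together with incident edges. Applied once — no iterative re-pruning,
    so surviving vertices may end up below the threshold."""
    if min_degree < 0:
        raise ValueError("min_degree must be >= 0")
    keep = [n for n, d in graph.degree() if d >= min_degree]
    return graph.subgraph(keep).copy()


def percentile_thresholds(
    graph: MovementGraph, n: int = 100, weighted: bool = False
) -> PercentileThresholds:
    """Nearest-rank percentile thresholds of the edge-distance distribution.

    By default each distinct edge contributes once; with ``weighted=True``
    each edge is replicated ``weight`` times, i.e. percentiles of observed
    movements rather than of distinct connections. m_s is the
    ceil(s*N/100)-th order statistic, so m_n is exactly the maximum.
    """
    dists = np.array([d for _, _, d in graph.edges(data="distance_km")])
    if dists.size == 0:
        raise ValueError("graph has no edges; percentile thresholds undefined")
    if weighted:
        w = np.array([w for _, _, w in graph.edges(data="weight")], dtype=int)
        dists = np.repeat(dists, w)
    dists.sort()
    size = dists.size
    m = tuple(
        float(dists[min(size, math.ceil(s * size / n)) - 1]) for s in range(1, n + 1)
    )
    return PercentileThresholds(m)


def percentile_graph(
    graph: MovementGraph, s: int, thresholds: PercentileThresholds
) -> MovementGraph:
    """The percentile graph G_s: same vertex set, only edges with
    d(e) <= m_s. Isolated vertices are retained so all scales share a
    common domain."""
    m_s = thresholds[s]  # validates range
    gs = nx.Graph()
    gs.add_nodes_from(graph.nodes(data=True))
    gs.add_edges_from(
        (u, v, data)
        for u, v, data in graph.edges(data=True)
        if data["distance_km"] <= m_s
    )
    return gs


def write_edgelist_csv(graph: MovementGraph, path) -> None:
    """Serialize as the documented ``u,v,weight,distance_km`` dialect."""
    import pandas as pd

    rows = sorted(
        (min(u, v), max(u, v), d["weight"], d["distance_km"])
        for u, v, d in graph.edges(data=True)
    )
    df = pd.DataFrame(rows, columns=["u", "v", "weight", "distance_km"])
    df.to_csv(path, index=False)


def read_edgelist_csv(path, locations: Sequence[Location] | None = None) -> MovementGraph:
    """Read the ``u,v,weight,distance_km`` dialect; if ``locations`` is given,
    isolated locations are added as vertices and coordinates attached."""
    import pandas as pd

    df = pd.read_csv(path, dtype={"u": str, "v": str})
    g = nx.Graph()
    if locations is not None:
        for l in locations:
            g.add_node(l.location_id, lat=l.lat, lon=l.lon)
    for r in df.itertuples(index=False):
        g.add_edge(r.u, r.v, weight=int(r.weight), distance_km=float(r.distance_km))
    return g
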