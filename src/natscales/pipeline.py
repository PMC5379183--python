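"""End-to-end orchestration: events -> movement graph -> per-percentile
partitions -> scale space -> natural scales -> boundaries.

Every stage is reproducible from ``RunConfig.random_seed``: community
detection run seeds derive deterministically from (seed, percentile,
run index), so re-running with identical inputs reproduces identical
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import communities, graph as graphmod, scales as scalesmod, voronoi
from .io import (
    Event,
    Location,
    RunConfig,
    assign_events_to_locations,
    normalize_labels,
    write_boundaries_geojson,
    write_partition_csv,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineRun:
    """All stage outputs of one pipeline execution."""

    config: RunConfig
    locations: dict
    graph: object
    pruned_graph: object
    thresholds: object
    tessellation: object
    raw_partitions: dict  # percentile -> partition (pre-smoothing)
    partitions: dict  # percentile -> smoothed partition
    scalespace: object
    breakpoints: list
    natural_scales: list
    prototypical_partitions: list  # smoothed, one per natural scale
    multiscale_partitions: list  # after tuple smoothing, one per natural scale
    boundaries: dict = field(default_factory=dict)  # scale index -> line geometries

    def results(self) -> dict:
        """The run's summary document (breakpoints, intervals, prototypes,
        distance thresholds)."""
        return {
            "n_percentiles": self.config.n_percentiles,
            "thresholds_km": list(self.thresholds.m),
            "breakpoints": list(self.breakpoints),
            "intervals": [list(ns.interval) for ns in self.natural_scales],
            "prototypical_scales": [ns.prototypical_percentile for ns in self.natural_scales],
            "distance_ranges_km": [list(ns.distance_range_km) for ns in self.natural_scales],
            "n_natural_scales": len(self.natural_scales),
        }


def partition_scale_spectrum(
    pruned,
    thresholds,
    tess,
    config: RunConfig,
) -> tuple[dict, dict]:
    """Best-of-N community detection plus smoothing for every percentile.

    Returns (raw partitions, smoothed partitions), keyed by percentile.
    """
    raw, smoothed = {}, {}
    for s in range(1, config.n_percentiles + 1):
        gs = graphmod.percentile_graph(pruned, s, thresholds)
        res = communities.detect_best_partition(
            gs,
            n_runs=config.n_partition_runs,
            seed=communities.derive_seed(config.random_seed, s),
        )
        raw[s] = res.partition
        smoothed[s] = normalize_labels(
            voronoi.smooth_partition(res.partition, tess, config.smoothing_max_sweeps)
        )
        if s % 20 == 0:
            logger.info(
                "scale %d: %d edges, %d communities (Q=%.3f)",
                s, gs.number_of_edges(), len(set(res.partition.values())), res.modularity,
            )
    return raw, smoothed


def run_pipeline(
    events: Sequence[Event],
    locations: Sequence[Location],
    config: RunConfig | None = None,
    out_dir=None,
) -> PipelineRun:
    """Execute the full natural-scales pipeline.

    Stages: nearest-location assignment -> co-occurrence graph -> degree
    pruning -> percentile thresholds -> per-percentile community detection
    and Voronoi smoothing -> Rand-similarity matrix -> breakpoint detection
    -> prototypical scales -> multi-scale tuple smoothing -> boundary
    extraction. Artifacts are written under ``out_dir`` when given.
    """
    config = config or RunConfig()
    loc_map = {l.location_id: l for l in locations}

    assignments = assign_events_to_locations(events, locations)
    logger.info("assigned %d events to %d locations", len(assignments), len(loc_map))

    g = graphmod.build_cooccurrence_graph([(u, l) for _, u, l in assignments], loc_map)
    pruned = graphmod.prune_low_degree(g, config.min_vertex_degree)
    logger.info(
        "graph: %d/%d vertices, %d/%d edges after degree-%d pruning",
        pruned.number_of_nodes(), g.number_of_nodes(),
        pruned.number_of_edges(), g.number_of_edges(), config.min_vertex_degree,
    )
    if pruned.number_of_edges() == 0:
        raise ValueError("pruned movement graph has no edges; nothing to scale")

    kept_locations = [loc_map[n] for n in sorted(pruned.nodes)]
    tess = voronoi.build_tessellation(kept_locations)
    thresholds = graphmod.percentile_thresholds(
        pruned, n=config.n_percentiles, weighted=config.weighted_percentiles
    )

    raw, smoothed = partition_scale_spectrum(pruned, thresholds, tess, config)
    ss = scalesmod.similarity_matrix(smoothed)
    breakpoints = scalesmod.detect_breakpoints(ss, config.min_interval_size)
    nat = scalesmod.natural_scales(ss, thresholds, config.min_interval_size, breakpoints)
    logger.info("breakpoints %s -> %d natural scales", breakpoints, len(nat))

    proto_parts = [smoothed[ns.prototypical_percentile] for ns in nat]
    multi = voronoi.smooth_multiscale(proto_parts, tess, config.smoothing_max_sweeps)

    boundaries = {
        k + 1: voronoi.extract_boundaries(tess, part) for k, part in enumerate(multi)
    }

    run = PipelineRun(
        config=config,
        locations=loc_map,
        graph=g,
        pruned_graph=pruned,
        thresholds=thresholds,
        tessellation=tess,
        raw_partitions=raw,
        partitions=smoothed,
        scalespace=ss,
        breakpoints=list(breakpoints),
        natural_scales=nat,
        prototypical_partitions=proto_parts,
        multiscale_partitions=multi,
        boundaries=boundaries,
    )
    if out_dir is not None:
        write_artifacts(run, out_dir)
    return run


def write_artifacts(run: PipelineRun, out_dir) -> None:
    """Persist results JSON, per-scale partition CSVs, the similarity
    matrix and boundary GeoJSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "results.json", "w") as fh:
        json.dump(run.results(), fh, indent=2)
    pd.DataFrame(
        run.scalespace.similarity,
        index=run.scalespace.percentiles,
        columns=run.scalespace.percentiles,
    ).to_csv(out / "similarity_matrix.csv")
    part_dir = out / "partitions"
    part_dir.mkdir(exist_ok=True)
    for s, part in run.partitions.items():
        write_partition_csv(part, part_dir / f"scale_{s:03d}.csv")
    segments = []
    for k, geoms in run.boundaries.items():
        segments.extend((k, geom) for geom in geoms)
        write_boundaries_geojson(
            [(k, geom) for geom in geoms], out / f"boundaries_scale_{k}.geojson"
        )
    write_boundaries_geojson(segments, out / "boundaries_multiscale.geojson")


def run_bipartition_report(
    pruned,
    locations: Mapping[str, Location],
    config: RunConfig | None = None,
):
    """Best-of-N detection on the full (percentile-100) graph followed by
    the exhaustive merge into two communities, with boundary extraction —
    the bipartite validation map.

    Returns (bipartition PartitionResult, boundary geometries).
    """
    config = config or RunConfig()
    best = communities.detect_best_partition(
        pruned, n_runs=config.n_partition_runs,
        seed=communities.derive_seed(config.random_seed, 101),
    )
    k = len(set(best.partition.values()))
    result = best if k < 2 else communities.exhaustive_bipartition(pruned, best.partition)
    kept = [locations[n] for n in sorted(pruned.nodes)]
    tess = voronoi.build_tessellation(kept)
    smoothed = voronoi.smooth_partition(result.partition, tess, config.smoothing_max_sweeps)
    bounds = voronoi.extract_boundaries(tess, smoothed)
    return result, bounds
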