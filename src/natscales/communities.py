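"""Modularity partitions of percentile graphs.

Community detection uses a Louvain-class heuristic (networkx's seeded
implementation). Because the heuristic is stochastic and approximate, each
graph is partitioned ``n_runs`` times (default 100) with run-indexed seeds
and the run attaining the highest weighted Newman–Girvan modularity is
kept. A separate exhaustive search merges an existing partition's
communities into the best two groups, for bipartite validation maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import Partition, normalize_labels

#: guard on the exhaustive merge enumeration (2^(k-1) - 1 candidates)
MAX_BIPARTITION_COMMUNITIES = 25


@dataclass(frozen=True)
class PartitionResult:
    partition: dict
    modularity: float
    n_runs: int
    seed: int


def derive_seed(*parts: int) -> int:
    """Deterministic child seed from (global seed, scale, run, ...) below 2^31."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def _communities(graph: nx.Graph, partition) -> list[set]:
    missing = set(graph.nodes) - set(partition)
    if missing:
        raise ValueError(f"partition does not cover vertices: {sorted(missing)[:5]}")
    groups: dict = {}
    for node in graph.nodes:
        groups.setdefault(partition[node], set()).add(node)
    return list(groups.values())


def modularity(graph: nx.Graph, partition) -> float:
    """Weighted Newman–Girvan modularity Q of a partition: the fraction of
    edge weight inside communities minus its expectation under the
    degree-preserving null model. Deterministic; 0 for edgeless graphs."""
    if graph.number_of_edges() == 0:
        _communities(graph, partition)  # still validate coverage
        return 0.0
    return float(nx.community.modularity(graph, _communities(graph, partition), weight="weight"))


def detect_best_partition(graph: nx.Graph, n_runs: int = 100, seed: int = 0) -> PartitionResult:
    """Best-of-``n_runs`` Louvain partition.

    Each run uses a seed derived from ``(seed, run index)``; the run with
    maximal modularity wins, ties going to the earliest run, so results are
    reproducible and modularity is non-decreasing in ``n_runs``. Isolated
    vertices come out as singleton communities. An empty graph yields an
    empty partition with modularity 0.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if graph.number_of_nodes() == 0:
        return PartitionResult({}, 0.0, n_runs, seed)
    best_part = None
    best_q = -np.inf
    for run in range(n_runs):
        run_seed = derive_seed(seed, run)
        comms = nx.community.louvain_communities(graph, weight="weight", seed=run_seed)
        part = {node: i for i, comm in enumerate(comms) for node in comm}
        q = modularity(graph, part)
        if q > best_q:
            best_q, best_part = q, part
    return PartitionResult(normalize_labels(best_part), float(best_q), n_runs, seed)


def exhaustive_bipartition(graph: nx.Graph, partition) -> PartitionResult:
    """Merge the k communities of ``partition`` into the best two groups.

    All 2^(k-1) - 1 ways of splitting the k communities into two non-empty
    groups are evaluated (community 0 of the canonical labelling anchors
    group 0); the merge with maximal modularity wins, ties going to the
    first candidate in enumeration order. Guarded at k <= 25.
    """
    part = normalize_labels(partition)
    k = len(set(part.values()))
    if k < 2:
        raise ValueError("bipartition requires a partition with k >= 2 communities")
    if k > MAX_BIPARTITION_COMMUNITIES:
        raise ValueError(
            f"k={k} communities exceeds the exhaustive-merge guard ({MAX_BIPARTITION_COMMUNITIES})"
        )
    labels = {node: lab for node, lab in part.items()}
    best_part = None
    best_q = -np.inf
    n_candidates = 0
    # mask bit i-1 set => community i joins group 1; community 0 stays in group 0
    for mask in range(1, 2 ** (k - 1)):
        merged = {
            node: (1 if lab > 0 and (mask >> (lab - 1)) & 1 else 0)
            for node, lab in labels.items()
        }
        q = modularity(graph, merged)
        n_candidates += 1
        if q > best_q:
            best_q, best_part = q, merged
    assert n_candidates == 2 ** (k - 1) - 1
    return PartitionResult(normalize_labels(best_part), float(best_q), n_candidates, 0)
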