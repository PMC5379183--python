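import numpy as np
import pytest

from natscales.io import Location


@pytest.fixture
def rng():
    return np.random.default_rng(20170404)


@pytest.fixture
def unit_square_locations():
    """Four seeds at the corners of a ~unit degree square."""
    return [
        Location("sw", 0.0, 0.0),
        Location("se", 0.0, 1.0),
        Location("nw", 1.0, 0.0),
        Location("ne", 1.0, 1.0),
    ]


@pytest.fixture
def grid3x3_locations():
    """3x3 lattice of seeds; Voronoi cells are rook-adjacent squares."""
    return [
        Location(f"g{r}{c}", float(r), float(c)) for r in range(3) for c in range(3)
    ]


def random_partition(rng, domain, k):
    """Random labelling of ``domain`` into at most k communities."""
    return {loc: int(lab) for loc, lab in zip(domain, rng.integers(0, k, len(domain)))}


def brute_force_rand(p, q):
    """O(n^2) all-pairs Rand index oracle: counts pairs classified
    concordantly (together in both or apart in both)."""
    domain = sorted(p)
    agree = total = 0
    for i in range(len(domain)):
        for j in range(i + 1, len(domain)):
            a, b = domain[i], domain[j]
            total += 1
            agree += (p[a] == p[b]) == (q[a] == q[b])
    return agree / total


def textbook_modularity(graph, partition):
    """Independent weighted Newman–Girvan formula:
    Q = sum_c [ w_in(c)/m - (d_c / 2m)^2 ] with m the total edge weight,
    w_in intra-community weight and d_c the community's weighted degree."""
    m = sum(d.get("weight", 1) for _, _, d in graph.edges(data=True))
    if m == 0:
        return 0.0
    labels = set(partition[n] for n in graph.nodes)
    q = 0.0
    for c in labels:
        members = {n for n in graph.nodes if partition[n] == c}
        w_in = sum(
            d.get("weight", 1)
            for u, v, d in graph.edges(data=True)
            if u in members and v in members
        )
        d_c = sum(
            d.get("weight", 1) * ((u in members) + (v in members))
            for u, v, d in graph.edges(data=True)
        )
        q += w_in / m - (d_c / (2 * m)) ** 2
    return q


def block_similarity_matrix(blocks, within=0.9, across=0.1):
    """Planted block-structured similarity matrix: ``blocks`` is a list of
    (lo, hi) 1-based inclusive intervals tiling 1..n."""
    n = max(hi for _, hi in blocks)
    mat = np.full((n, n), across)
    for lo, hi in blocks:
        mat[lo - 1 : hi, lo - 1 : hi] = within
    np.fill_diagonal(mat, 1.0)
    return mat


@pytest.fixture(scope="session")
def planted_world():
    """Canonical two-level planted world: 2 regions x 3 towns x 15 locations."""
    from natscales import synthetic

    return synthetic.generate_world(synthetic.WorldParams(), seed=0)


@pytest.fixture(scope="session")
def planted_run(planted_world):
    """One full pipeline execution on the canonical planted dataset
    (500 users x 10 movements, best-of-20 community detection), shared
    across test modules because it takes tens of seconds."""
    from natscales import pipeline, synthetic
    from natscales.io import RunConfig

    events = synthetic.generate_events(planted_world, seed=1000)
    config = RunConfig(n_partition_runs=20, random_seed=0)
    return pipeline.run_pipeline(events, planted_world.locations, config)
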