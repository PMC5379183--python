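"""Partition similarity across the scale spectrum, phase-transition
detection and natural scales.

Similarity between the partitions of two scales is the Rand index δ: the
fraction of unordered location pairs classified concordantly (together in
both partitions, or apart in both). Arranging δ for every pair of
percentiles gives a similarity matrix whose block structure reveals
ranges of mutually similar scales.

Interval separation σ scores a candidate set of breakpoints: the
size-weighted mean within-interval similarity divided by the maximum
similarity between the consecutive partitions straddling a breakpoint.
A greedy search adds breakpoints while σ strictly improves, subject to a
minimum interval size that stops noisy outlying percentiles from being
isolated as spurious scales. Each resulting interval — a natural scale —
is summarised by its prototypical percentile, the one whose partition is
most similar to all others in the interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distance import haversine_km
from .graph import PercentileThresholds
from .io import Partition


# ---------------------------------------------------------------------------
# Rand similarity
# ---------------------------------------------------------------------------

def pair_agreement(partition: Mapping, i, j) -> int:
    """μ(i, j): 1 if locations i and j share a community, else 0."""
    if i not in partition or j not in partition:
        raise ValueError(f"locations {i!r}, {j!r} must both be in the partition domain")
    return int(partition[i] == partition[j])


def rand_similarity(p: Mapping, q: Mapping) -> float:
    """Rand index δ ∈ [0, 1] between two partitions of the same domain.

    δ = (number of concordant unordered pairs) / (|V| choose 2), computed
    through the contingency-table identity
    agree = C(n,2) + 2·Σ_ij C(n_ij,2) − Σ_i C(a_i,2) − Σ_j C(b_j,2),
    which is exact in integer arithmetic. Label numbering is immaterial.
    """
    if set(p) != set(q):
        raise ValueError("partitions must share the same domain")
    domain = sorted(p)
    n = len(domain)
    if n < 2:
        raise ValueError("Rand index needs a domain of at least 2 locations")
    la = pd.factorize(np.array([p[k] for k in domain]))[0]
    lb = pd.factorize(np.array([q[k] for k in domain]))[0]
    cont = np.zeros((la.max() + 1, lb.max() + 1), dtype=np.int64)
    np.add.at(cont, (la, lb), 1)

    def c2(x):
        return x * (x - 1) // 2

    total = c2(n)
    agree = total + 2 * int(c2(cont).sum()) - int(c2(cont.sum(axis=1)).sum()) - int(
        c2(cont.sum(axis=0)).sum()
    )
    return agree / total


@dataclass
class ScaleSpace:
    """Per-percentile partitions over a common domain and their pairwise
    Rand-similarity matrix (symmetric, unit diagonal)."""

    partitions: dict
    similarity: np.ndarray

    @property
    def percentiles(self) -> list:
        return sorted(self.partitions)

    @property
    def n(self) -> int:
        return len(self.partitions)

    def delta(self, s: int, s2: int) -> float:
        """δ between the partitions at (1-based) percentiles s and s2."""
        return float(self.similarity[s - 1, s2 - 1])


def similarity_matrix(partitions: Mapping[int, Mapping] | Sequence[Mapping]) -> ScaleSpace:
    """δ for every pair of scales. ``partitions`` maps percentile -> partition
    (or is a sequence taken as percentiles 1..n); all must share one domain."""
    if not isinstance(partitions, Mapping):
        partitions = {s + 1: p for s, p in enumerate(partitions)}
    keys = sorted(partitions)
    n = len(keys)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = rand_similarity(partitions[keys[i]], partitions[keys[j]])
    return ScaleSpace(dict(partitions), mat)


def normalized_dissimilarity(scalespace: ScaleSpace) -> np.ndarray:
    """(1 − δ) rescaled by its maximum entry to [0, 1]: 0 is a perfect
    match, 1 the largest dissimilarity observed. A monotone transform, so
    entry ordering is preserved. Degenerate (all partitions identical)
    input returns all zeros with a warning."""
    diss = 1.0 - scalespace.similarity
    mx = diss.max()
    if mx <= 0.0:
        warnings.warn("all partitions identical; normalized dissimilarity is degenerate")
        return np.zeros_like(diss)
    return diss / mx


# ---------------------------------------------------------------------------
# Breakpoints and interval separation
# ---------------------------------------------------------------------------

def intervals_from_breakpoints(breakpoints: Sequence[int], n: int) -> list[tuple[int, int]]:
    """Closed percentile intervals implied by interior breakpoints: with
    B = {b_1 < ... < b_k} ⊂ (1, n], the intervals are [1, b_1−1], ...,
    [b_k, n]. They partition 1..n."""
    bounds = [1, *sorted(breakpoints), n + 1]
    if any(b <= 1 or b > n for b in breakpoints):
        raise ValueError("interior breakpoints must lie in (1, n]")
    if len(set(bounds)) != len(bounds):
        raise ValueError("duplicate breakpoints")
    return [(bounds[i], bounds[i + 1] - 1) for i in range(len(bounds) - 1)]


def _within_mean(similarity: np.ndarray, lo: int, hi: int) -> float:
    """Mean δ over unordered scale pairs inside [lo, hi] (1-based,
    inclusive); a singleton interval contributes similarity 1."""
    size = hi - lo + 1
    if size == 1:
        return 1.0
    block = similarity[lo - 1 : hi, lo - 1 : hi]
    iu = np.triu_indices(size, k=1)
    return float(block[iu].mean())


def interval_separation(scalespace: ScaleSpace, breakpoints: Sequence[int]) -> float:
    """Interval separation σ for a breakpoint set.

    Numerator: interval-size-weighted mean of within-interval similarity
    (all unordered pairs per interval; singletons count as 1). Denominator:
    max over breakpoints b of δ(P_{b−1}, P_b), the similarity of the
    consecutive partitions straddling b. Returns +inf when the denominator
    is zero. Undefined (error) without at least one interior breakpoint.
    """
    breakpoints = sorted(breakpoints)
    if not breakpoints:
        raise ValueError("sigma is undefined with no interior breakpoint (single interval)")
    sim = scalespace.similarity
    n = scalespace.n
    intervals = intervals_from_breakpoints(breakpoints, n)
    weights = np.array([hi - lo + 1 for lo, hi in intervals], dtype=float)
    within = np.array([_within_mean(sim, lo, hi) for lo, hi in intervals])
    numerator = float((weights * within).sum() / weights.sum())
    denominator = max(float(sim[b - 2, b - 1]) for b in breakpoints)
    if denominator == 0.0:
        return float("inf")
    return numerator / denominator


def _feasible_positions(breakpoints: list[int], n: int, min_size: int) -> list[int]:
    """Positions where inserting one more breakpoint keeps every interval
    at least ``min_size`` long."""
    out = []
    for b in range(2, n + 1):
        if b in breakpoints:
            continue
        trial = sorted([*breakpoints, b])
        if all(hi - lo + 1 >= min_size for lo, hi in intervals_from_breakpoints(trial, n)):
            out.append(b)
    return out


def detect_breakpoints(scalespace: ScaleSpace, min_interval_size: int = 5) -> list[int]:
    """Greedy phase-transition detection.

    The first breakpoint is the feasible position maximising σ; each
    following iteration evaluates every feasible additional position and
    adds the σ-maximising one only if it strictly increases σ. Position
    ties break toward the smaller percentile. Needs at least
    2·min_interval_size percentiles.
    """
    n = scalespace.n
    if n < 2 * min_interval_size:
        raise ValueError(
            f"need >= {2 * min_interval_size} percentiles for min_interval_size={min_interval_size}"
        )
    breakpoints: list[int] = []
    best_sigma = -np.inf
    while True:
        candidates = _feasible_positions(breakpoints, n, min_interval_size)
        if not candidates:
            if not breakpoints:
                raise ValueError("no feasible breakpoint position")
            break
        trial_sigma, trial_b = max(
            ((interval_separation(scalespace, [*breakpoints, b]), -b) for b in candidates),
        )
        trial_b = -trial_b
        if trial_sigma > best_sigma:
            breakpoints = sorted([*breakpoints, trial_b])
            best_sigma = trial_sigma
        else:
            break
    return breakpoints


# ---------------------------------------------------------------------------
# Natural scales
# ---------------------------------------------------------------------------

def prototypical_scale(scalespace: ScaleSpace, interval: tuple[int, int]) -> int:
    """The percentile of the interval whose partition is most similar to
    all others in the interval (argmax of the within-interval δ row sum);
    ties break toward the smaller percentile."""
    lo, hi = interval
    sim = scalespace.similarity
    best_s, best_total = lo, -np.inf
    for s in range(lo, hi + 1):
        total = sum(sim[s - 1, s2 - 1] for s2 in range(lo, hi + 1) if s2 != s)
        if total > best_total:
            best_s, best_total = s, total
    return best_s


@dataclass(frozen=True)
class NaturalScale:
    """A contiguous percentile interval between phase transitions, its
    prototypical percentile and the absolute distance range it spans.

    ``distance_range_km`` is half-open (lower, upper] — the first scale is
    closed below at 0 — so every movement distance maps to exactly one
    scale."""

    interval: tuple[int, int]
    prototypical_percentile: int
    distance_range_km: tuple[float, float]


def natural_scales(
    scalespace: ScaleSpace,
    thresholds: PercentileThresholds,
    min_interval_size: int = 5,
    breakpoints: Sequence[int] | None = None,
) -> list[NaturalScale]:
    """Detect breakpoints (unless given) and assemble the natural scales,
    smallest distance range first."""
    if breakpoints is None:
        breakpoints = detect_breakpoints(scalespace, min_interval_size)
    out = []
    for lo, hi in intervals_from_breakpoints(breakpoints, scalespace.n):
        lower = 0.0 if lo == 1 else thresholds[lo - 1]
        out.append(
            NaturalScale(
                interval=(lo, hi),
                prototypical_percentile=prototypical_scale(scalespace, (lo, hi)),
                distance_range_km=(lower, thresholds[hi]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# User contributions per scale
# ---------------------------------------------------------------------------

def user_scale_contributions(
    user_locations: Mapping[str, set],
    locations: Mapping,
    scales: Sequence[NaturalScale],
) -> pd.DataFrame:
    """Assign each user the set of natural scales they contribute to.

    A user contributes to a scale when at least one unordered pair of
    their distinct visited locations lies in that scale's distance range
    (half-open (lower, upper]; the first scale includes 0). A user with a
    single visited location contributes to no scale. Activity is the
    number of distinct visited locations.

    Returns one row per user: ``user_id``, ``scales`` (e.g. "12" for
    scales 1 and 2, "" for none), ``n_scales``, ``activity``.
    """
    rows = []
    for user_id in sorted(user_locations):
        visited = sorted(user_locations[user_id])
        contributed = set()
        if len(visited) >= 2:
            lats = np.array([locations[l].lat for l in visited])
            lons = np.array([locations[l].lon for l in visited])
            iu = np.triu_indices(len(visited), k=1)
            dists = haversine_km(lats[iu[0]], lons[iu[0]], lats[iu[1]], lons[iu[1]])
            dists = np.atleast_1d(dists)
            for k, sc in enumerate(scales, start=1):
                lower, upper = sc.distance_range_km
                if k == 1:
                    hit = (dists >= 0.0) & (dists <= upper)
                else:
                    hit = (dists > lower) & (dists <= upper)
                if bool(hit.any()):
                    contributed.add(k)
        rows.append(
            {
                "user_id": user_id,
                "scales": "".join(str(k) for k in sorted(contributed)),
                "n_scales": len(contributed),
                "activity": len(visited),
            }
        )
    return pd.DataFrame(rows)


def scale_set_summary(contributions: pd.DataFrame) -> pd.DataFrame:
    """Aggregate user counts and mean activity per contributed scale set;
    ``rel_activity`` is the set's mean activity over the maximum set mean."""
    g = (
        contributions.groupby("scales")
        .agg(n_users=("user_id", "size"), mean_activity=("activity", "mean"))
        .reset_index()
    )
    mx = g["mean_activity"].max()
    g["rel_activity"] = g["mean_activity"] / mx if mx > 0 else 0.0
    return g.sort_values("scales").reset_index(drop=True)
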