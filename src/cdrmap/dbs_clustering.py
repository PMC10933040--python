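"""DBSCAN-based selection (DBS) of loop conformation clusters.

DBSCAN on a precomputed distance matrix needs two parameters: min-points
(square root of the group size, or of half the group size) and epsilon.
Epsilon is read off the elbow of the sorted k-th-nearest-neighbour distance
curve for each K in 2..5, giving four candidate clusterings; the run whose
cluster count matches its K is selected (largest such K), falling back to
the closest match at the highest K.  The resulting clusters are DBS
clusters; noise points carry label -1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .metrics import DistanceMatrix

logger = logging.getLogger(__name__)

SQRT_N = "SQRT_N"
SQRT_N_HALF = "SQRT_N_HALF"

NOISE = -1

K_RANGE = (2, 3, 4, 5)


@dataclass(frozen=True)
class ClusteringParams:
    min_points: int
    epsilon: float
    k_used: int
    min_points_rule: str


@dataclass
class ClusteringResult:
    ids: list[str]
    labels: np.ndarray  # 1..n_clusters, NOISE for unassigned
    params: ClusteringParams
    n_clusters: int
    medoids: dict[int, str] = field(default_factory=dict)
    trace: list[dict] = field(default_factory=list)

    def members(self, label: int) -> list[str]:
        return [i for i, l in zip(self.ids, self.labels) if l == label]

    def cluster_labels(self) -> list[int]:
        return sorted(int(l) for l in set(self.labels) if l != NOISE)


def min_points(n: int, rule: str = SQRT_N_HALF) -> int:
    """Min-points for a group of n loops: round(sqrt(n)) or round(sqrt(n/2)).

    Rounding is round-half-even; the result is floored at 2.
    """
    if n < 4:
        raise ValueError(f"too few loops to cluster (n={n})")
    if rule == SQRT_N:
        value = round(np.sqrt(n))
    elif rule == SQRT_N_HALF:
        value = round(np.sqrt(n / 2))
    else:
        raise ValueError(f"unknown min-points rule {rule!r}")
    return max(2, int(value))


def kth_nn_curve(D: DistanceMatrix, k: int) -> np.ndarray:
    """Every point's k-th smallest distance to another point, sorted ascending."""
    n = len(D)
    if not 2 <= k <= 5:
        raise ValueError(f"K must be in 2..5, got {k}")
    if k >= n:
        raise ValueError(f"K={k} requires more than {k} points (n={n})")
    values = np.sort(D.values, axis=1)  # column 0 is the self-distance 0
    return np.sort(values[:, k])


def elbow_epsilon(curve: np.ndarray) -> float:
    """Elbow of an ascending k-distance curve, used as DBSCAN epsilon.

    The elbow is the point of maximum perpendicular distance to the chord
    joining the first and last curve points, on the convex (below-chord) side
    — the knee where an ascending k-distance plot turns upward (Kneedle-style
    for an increasing convex curve).  Ties resolve to the smallest index.  A
    curve with no below-chord point uses the bend above the chord instead; a
    constant curve has no elbow and its value is returned with a warning.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.size < 3:
        raise ValueError("curve must have at least 3 points")
    x = np.arange(curve.size, dtype=float)
    dx = x[-1] - x[0]
    dy = curve[-1] - curve[0]
    norm = np.hypot(dx, dy)
    if dy == 0.0 and np.all(curve == curve[0]):
        warnings.warn("constant k-distance curve: no elbow", stacklevel=2)
        return float(curve[0])
    # signed distance to the chord; positive where the curve dips below it
    signed = (dy * (x - x[0]) - dx * (curve - curve[0])) / norm
    if signed.max() > 0:
        return float(curve[int(np.argmax(signed))])
    return float(curve[int(np.argmax(-signed))])


def dbscan_precomputed(
    D: DistanceMatrix, epsilon: float, min_points: int
) -> np.ndarray:
    """Standard DBSCAN on a precomputed distance matrix.

    A point is core iff at least ``min_points`` points (itself included) lie
    within ``epsilon`` (inclusive).  Clusters are the connected components of
    core points under epsilon-reachability; border points join the first core
    cluster reaching them in ID-sorted order; all others are labelled -1.
    Cluster numbering starts at 1 in ID-sorted discovery order.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    n = len(D)
    within = D.values <= epsilon
    core = within.sum(axis=1) >= min_points
    labels = np.full(n, NOISE, dtype=int)
    if not core.any():
        return labels

    core_idx = np.flatnonzero(core)
    adj = csr_matrix(within[np.ix_(core_idx, core_idx)])
    n_comp, comp = connected_components(adj, directed=False)

    # Number components deterministically by ID-sorted first core member.
    id_order = np.argsort(np.array(D.ids, dtype=object)[core_idx], kind="stable")
    relabel: dict[int, int] = {}
    for pos in id_order:
        c = comp[pos]
        if c not in relabel:
            relabel[c] = len(relabel) + 1
    for pos, ci in enumerate(core_idx):
        labels[ci] = relabel[comp[pos]]

    # Border points: non-core within epsilon of a core point; join the first
    # core point reaching them in ID-sorted order.
    sorted_core = core_idx[np.argsort(np.array(D.ids, dtype=object)[core_idx], kind="stable")]
    for i in np.flatnonzero(~core):
        for ci in sorted_core:
            if within[i, ci]:
                labels[i] = labels[ci]
                break
    return labels


def _renumber_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k by descending size (ties keep original order)."""
    out = np.full_like(labels, NOISE)
    uniq = [l for l in np.unique(labels) if l != NOISE]
    sizes = {l: int((labels == l).sum()) for l in uniq}
    order = sorted(uniq, key=lambda l: (-sizes[l], l))
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out


def select_clustering(
    D: DistanceMatrix, rule: str = SQRT_N_HALF
) -> ClusteringResult:
    """Run the full DBS protocol on a distance matrix.

    For each K in 2..5 the elbow of the K-NN distance curve gives epsilon and
    DBSCAN runs with the rule-derived min-points; the run whose cluster count
    equals its K wins (largest K if several), otherwise the closest count at
    the highest K.  Cluster labels are renumbered by descending size and
    medoids recorded per cluster.
    """
    from .cluster_profiles import medoid  # local import, no cycle at load time

    n = len(D)
    mp = min_points(n, rule)
    runs: list[dict] = []
    for k in K_RANGE:
        if k >= n:
            continue
        eps = elbow_epsilon(kth_nn_curve(D, k))
        if eps <= 0:
            positive = D.values[D.values > 0]
            eps = float(positive.min()) if positive.size else 1e-12
        labels = dbscan_precomputed(D, eps, mp)
        n_clusters = len(set(labels) - {NOISE})
        runs.append(
            {"k": k, "epsilon": eps, "n_clusters": n_clusters, "labels": labels}
        )
    if not runs:
        raise ValueError(f"too few loops to cluster (n={n})")

    exact = [r for r in runs if r["n_clusters"] == r["k"]]
    if exact:
        chosen = max(exact, key=lambda r: r["k"])
    else:
        chosen = min(runs, key=lambda r: (abs(r["n_clusters"] - r["k"]), -r["k"]))
    for r in runs:
        r["chosen"] = r is chosen
        logger.info(
            "DBS K=%d eps=%.4f clusters=%d%s",
            r["k"], r["epsilon"], r["n_clusters"], " *" if r["chosen"] else "",
        )

    labels = _renumber_by_size(chosen["labels"])
    params = ClusteringParams(mp, chosen["epsilon"], chosen["k"], rule)
    result = ClusteringResult(
        ids=list(D.ids),
        labels=labels,
        params=params,
        n_clusters=len(set(labels) - {NOISE}),
        trace=[{k: v for k, v in r.items() if k != "labels"} for r in runs],
    )
    for label in result.cluster_labels():
        result.medoids[label] = medoid(D, result.members(label))
    return result
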