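"""Independent reference implementations used only to check the package.

These deliberately use different algorithms from the library code: a
quaternion eigenvalue method for superposition RMSD, explicit enumeration of
monotone warping paths for DTW, and a naive transitive-closure DBSCAN.
"""

from __future__ import annotations

import numpy as np


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal superposition RMSD via the Horn quaternion eigenvalue method."""
    a = np.asarray(mobile, float) - np.mean(mobile, axis=0)
    b = np.asarray(reference, float) - np.mean(reference, axis=0)
    n = a.shape[0]
    s = a.T @ b
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    K = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(K).max()
    g = np.sum(a**2) + np.sum(b**2)
    return float(np.sqrt(max(0.0, g - 2.0 * lam) / n))


def brute_force_dtw(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """Minimal warping-path total squared cost by explicit path enumeration.

    Steps (1,0), (0,1), (1,1) from (0,0) to (n-1,m-1).  Returns the optimal
    total cost and whether the strict diagonal path attains it (only defined
    for equal lengths; False otherwise).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n, m = a.shape[0], b.shape[0]
    cost = np.array([[float(np.sum((a[i] - b[j]) ** 2)) for j in range(m)] for i in range(n)])

    best = [np.inf]

    def walk(i: int, j: int, total: float) -> None:
        total += cost[i, j]
        if total >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = total
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, total)
        if i + 1 < n:
            walk(i + 1, j, total)
        if j + 1 < m:
            walk(i, j + 1, total)

    walk(0, 0, 0.0)
    diagonal_optimal = False
    if n == m:
        diag = float(sum(cost[i, i] for i in range(n)))
        diagonal_optimal = abs(diag - best[0]) <= 1e-12 * max(1.0, diag)
    return best[0], diagonal_optimal


def brute_force_dbscan(
    values: np.ndarray, ids: list[str], epsilon: float, min_points: int
) -> np.ndarray:
    """Reference DBSCAN: reachability closure by boolean matrix iteration.

    Core iff >= min_points within epsilon inclusive (self counted); core
    clusters are the transitive closure of core-core epsilon adjacency;
    border points take the cluster of the first core point within epsilon in
    ID-sorted order.
    """
    n = values.shape[0]
    within = values <= epsilon
    core = within.sum(axis=1) >= min_points
    labels = np.full(n, -1, dtype=int)
    core_idx = np.flatnonzero(core)
    if core_idx.size == 0:
        return labels
    adj = within[np.ix_(core_idx, core_idx)].astype(bool)
    reach = adj.copy()
    while True:
        new = reach | ((reach.astype(int) @ adj.astype(int)) > 0)
        if (new == reach).all():
            break
        reach = new
    assigned: dict[int, int] = {}
    next_label = 1
    for pos in sorted(range(core_idx.size), key=lambda p: ids[core_idx[p]]):
        if pos in assigned:
            continue
        component = np.flatnonzero(reach[pos])
        for q in component:
            assigned[int(q)] = next_label
        next_label += 1
    for pos, ci in enumerate(core_idx):
        labels[ci] = assigned[pos]
    order = sorted(core_idx, key=lambda ci: ids[ci])
    for i in np.flatnonzero(~core):
        for ci in order:
            if within[i, ci]:
                labels[i] = labels[ci]
                break
    return labels


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """Partition identity up to cluster relabeling; noise (-1) must match."""
    a = np.asarray(a)
    b = np.asarray(b)
    if (a == -1).tolist() != (b == -1).tolist():
        return False
    mapping: dict[int, int] = {}
    for x, y in zip(a, b):
        if x == -1:
            continue
        if x in mapping and mapping[x] != y:
            return False
        mapping[x] = y
    return len(set(mapping.values())) == len(mapping)
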