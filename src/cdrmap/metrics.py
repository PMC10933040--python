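"""Distances between CDR loop backbones.

Loops already superposed onto a common template are compared by plain
common-frame RMSD (no per-pair refit, which makes it a true metric on the
template frame).  Loops of different lengths are compared by dynamic time
warping over their backbone atom sequences, normalized so the score is on
the RMSD scale: the squared raw score is divided by the larger atom count
and the square root taken (for a 9- vs 8-residue pair the divisor is 27,
nine residues of two carbons and one nitrogen each).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .types import LoopRecord

RMSD = "RMSD"
DTW_NORM = "DTW_NORM"

#: Loops are analysed in consecutive batches of at most this many.
DEFAULT_BATCH_SIZE = 42_000


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances over an ordered set of loop IDs."""

    ids: list[str]
    values: np.ndarray
    metric: str = RMSD

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if (self.values < -1e-12).any():
            raise ValueError("distance matrix has negative entries")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal is not zero")
        self._index = {i: k for k, i in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, loop_id: str) -> int:
        return self._index[loop_id]

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self._index[i] for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.metric)


def backbone_array(loop: LoopRecord) -> np.ndarray:
    """Flatten a loop to its ordered (3L, 3) backbone points (N, CA, C)."""
    return loop.backbone.reshape(-1, 3)


def rmsd_common_frame(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between two equal-length point lists already in the same frame."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(
            f"point counts differ ({a.shape[0]} vs {b.shape[0]}); "
            "use dtw_normalized for mismatched lengths"
        )
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Dynamic time warping
# ---------------------------------------------------------------------------

def _dtw_cost_py(a: np.ndarray, b: np.ndarray) -> float:
    n, m = a.shape[0], b.shape[0]
    big = np.inf
    prev = np.full(m + 1, big)
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur = np.full(m + 1, big)
        ai = a[i - 1]
        for j in range(1, m + 1):
            d = ai - b[j - 1]
            cost = d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = cost + best
        prev = cur
    return float(prev[m])


try:  # numba gives a ~100x faster DP kernel; the python fallback is exact
    from numba import njit

    _dtw_cost = njit(cache=False)(_dtw_cost_py)
except Exception:  # pragma: no cover
    _dtw_cost = _dtw_cost_py


def dtw_raw(a: np.ndarray, b: np.ndarray) -> float:
    """Raw DTW score: sqrt of the optimal warping-path total squared cost.

    Classic step set {(1,0),(0,1),(1,1)}, per-step cost = squared Euclidean
    distance between the aligned 3D points; no window or slope constraint.
    """
    a = np.ascontiguousarray(a, dtype=float)
    b = np.ascontiguousarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty point list")
    return float(np.sqrt(_dtw_cost(a, b)))


def dtw_normalized(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized DTW: sqrt(raw^2 / max(|a|, |b|)), on the RMSD scale."""
    raw = dtw_raw(a, b)
    n_max = max(np.asarray(a).shape[0], np.asarray(b).shape[0])
    return float(np.sqrt(raw * raw / n_max))


def dtw_normalization_divisor(n_a: int, n_b: int) -> int:
    """The atom count dividing the squared raw score: max of the two."""
    return max(n_a, n_b)


# ---------------------------------------------------------------------------
# Pairwise matrices
# ---------------------------------------------------------------------------

def _rmsd_matrix(loops: Sequence[LoopRecord]) -> np.ndarray:
    flat = np.stack([backbone_array(lp).ravel() for lp in loops])
    n_atoms = loops[0].backbone.shape[0] * 3
    return squareform(pdist(flat) / np.sqrt(n_atoms))


def _dtw_matrix(loops: Sequence[LoopRecord]) -> np.ndarray:
    arrays = [np.ascontiguousarray(backbone_array(lp)) for lp in loops]
    n = len(arrays)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = dtw_normalized(arrays[i], arrays[j])
    return out


def pairwise_matrix(
    loops: Sequence[LoopRecord],
    metric: str = RMSD,
    batch_size: int = DEFAULT_BATCH_SIZE,
) -> DistanceMatrix | list[DistanceMatrix]:
    """Full symmetric distance matrix over a group of loops.

    With more loops than ``batch_size`` the group is partitioned in input
    order into consecutive batches, each yielding an independent matrix
    (batches never mix); the return value is then a list of matrices.
    """
    if not loops:
        raise ValueError("no loops")
    if metric not in (RMSD, DTW_NORM):
        raise ValueError(f"unknown metric {metric!r}")
    if metric == RMSD:
        lengths = {lp.length for lp in loops}
        if len(lengths) > 1:
            raise ValueError(
                f"RMSD requires uniform loop length, got {sorted(lengths)}; "
                "use DTW_NORM for mixed lengths"
            )

    def one(batch: Sequence[LoopRecord]) -> DistanceMatrix:
        values = _rmsd_matrix(batch) if metric == RMSD else _dtw_matrix(batch)
        return DistanceMatrix([lp.loop_id for lp in batch], values, metric)

    if len(loops) <= batch_size:
        return one(loops)
    return [
        one(loops[i : i + batch_size]) for i in range(0, len(loops), batch_size)
    ]
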