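"""2D multidimensional scaling of loop distance matrices.

Classical (Torgerson) MDS: double-centre the squared distances, take the top
two eigenpairs.  Deterministic — no iteration or seed — and exact for any
configuration realizable in two Euclidean dimensions.  A landmark variant
embeds only m landmark points exactly and places the rest by distance-based
triangulation, for groups too large to eigendecompose comfortably.  Axes are
unitless (MDS1, MDS2); embeddings are only meaningful up to rotation,
reflection and translation, so comparisons go through pairwise distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .metrics import DistanceMatrix

DEFAULT_LANDMARKS = 500


@dataclass
class Embedding2D:
    ids: list[str]
    coords: np.ndarray  # (n, 2)
    stress: float

    def pairwise_distances(self) -> np.ndarray:
        return squareform(pdist(self.coords))


def _stress(D: np.ndarray, coords: np.ndarray) -> float:
    emb = squareform(pdist(coords))
    denom = np.sum(D**2)
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((D - emb) ** 2) / denom))


def classical_mds(D: DistanceMatrix) -> Embedding2D:
    """Torgerson MDS to 2D with negative eigenvalues clamped to zero."""
    n = len(D)
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    sq = D.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ sq @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1][:2]
    lam = np.clip(eigvals[order], 0.0, None)
    coords = eigvecs[:, order] * np.sqrt(lam)
    return Embedding2D(list(D.ids), coords, _stress(D.values, coords))


def landmark_mds(
    D_landmarks: DistanceMatrix,
    d_to_landmarks: np.ndarray,
    other_ids: list[str] | None = None,
) -> Embedding2D:
    """Classical MDS on landmarks plus triangulation of the remaining points.

    ``d_to_landmarks`` holds, per non-landmark point, its distances to every
    landmark (shape (n_other, m)).  With zero non-landmark points this
    coincides with :func:`classical_mds` on the landmarks.
    """
    m = len(D_landmarks)
    if m < 3:
        raise ValueError(f"need at least 3 landmarks, got {m}")
    sq = D_landmarks.values**2
    J = np.eye(m) - np.ones((m, m)) / m
    B = -0.5 * J @ sq @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1][:2]
    lam = np.clip(eigvals[order], 0.0, None)
    vecs = eigvecs[:, order]
    land_coords = vecs * np.sqrt(lam)

    d_to_landmarks = np.atleast_2d(np.asarray(d_to_landmarks, dtype=float))
    if d_to_landmarks.size == 0:
        coords = land_coords
        ids = list(D_landmarks.ids)
    else:
        if d_to_landmarks.shape[1] != m:
            raise ValueError("d_to_landmarks must have one column per landmark")
        mu = sq.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_sqrt = np.where(lam > 1e-12, 1.0 / np.sqrt(lam), 0.0)
        # x = diag(1/sqrt(lam)) V^T (-(delta^2 - mu)/2), exact for landmarks
        b = -0.5 * (d_to_landmarks**2 - mu)
        other_coords = (b @ vecs) * inv_sqrt
        coords = np.vstack([land_coords, other_coords])
        ids = list(D_landmarks.ids) + list(
            other_ids
            if other_ids is not None
            else [f"point{i}" for i in range(other_coords.shape[0])]
        )

    # stress over the distances actually supplied (landmark block + spokes)
    emb_land = squareform(pdist(land_coords))
    num = np.sum((D_landmarks.values - emb_land) ** 2)
    den = np.sum(D_landmarks.values**2)
    if d_to_landmarks.size:
        spoke = np.linalg.norm(
            coords[m:, None, :] - land_coords[None, :, :], axis=2
        )
        num += np.sum((d_to_landmarks - spoke) ** 2)
        den += np.sum(d_to_landmarks**2)
    stress = float(np.sqrt(num / den)) if den > 0 else 0.0
    return Embedding2D(ids, coords, stress)


def embed(D: DistanceMatrix, max_landmarks: int = DEFAULT_LANDMARKS) -> Embedding2D:
    """Embed a matrix, switching to landmark MDS above ``max_landmarks``.

    Landmarks are the first ``max_landmarks`` IDs after sorting, so the
    choice is deterministic; the embedding is returned in input ID order.
    """
    if len(D) <= max_landmarks:
        return classical_mds(D)
    sorted_ids = sorted(D.ids)
    land_ids = sorted_ids[:max_landmarks]
    other_ids = [i for i in D.ids if i not in set(land_ids)]
    land_idx = [D.index(i) for i in land_ids]
    other_idx = [D.index(i) for i in other_ids]
    emb = landmark_mds(
        D.submatrix(land_ids),
        D.values[np.ix_(other_idx, land_idx)],
        other_ids=other_ids,
    )
    pos = {i: k for k, i in enumerate(emb.ids)}
    coords = emb.coords[[pos[i] for i in D.ids]]
    return Embedding2D(list(D.ids), coords, emb.stress)
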