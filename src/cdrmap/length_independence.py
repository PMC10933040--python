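"""Cross-length analysis of loop clusters.

Somatic-hypermutation insertions can carry a canonical loop shape of length
L into loops of length L+1, so a cluster's nearest conformational neighbour
may live at a different length (length independence).  Loops of adjacent
lengths are compared in one joint normalized-DTW matrix; a novel cluster is
flagged length-independent when its medoid is closer to a shorter-length
cluster medoid than to any cluster of its own length, and that nearest
shorter cluster is named its origin.  The sequence-level signature is a flat
(unconserved) logo column inserted into the origin's conserved motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cluster_profiles import ClusterProfile, Novelty, insertion_position
from .metrics import DTW_NORM, DistanceMatrix, backbone_array, dtw_normalized
from .types import LoopRecord


def joint_cross_length_matrix(
    loops_a: Sequence[LoopRecord], loops_b: Sequence[LoopRecord]
) -> DistanceMatrix:
    """Normalized-DTW matrix over the union of two (template-aligned) groups.

    Both groups must be the same CDR type; lengths may differ, every pair
    (matched and mismatched) is scored with normalized DTW.
    """
    loops = list(loops_a) + list(loops_b)
    cdrs = {lp.cdr for lp in loops}
    if len(cdrs) > 1:
        raise ValueError(f"mixed CDR types in cross-length analysis: {sorted(cdrs)}")
    arrays = [np.ascontiguousarray(backbone_array(lp)) for lp in loops]
    n = len(arrays)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = dtw_normalized(arrays[i], arrays[j])
    return DistanceMatrix([lp.loop_id for lp in loops], values, DTW_NORM)


@dataclass
class OriginMatchReport:
    novel_cluster: int
    same_length_distances: dict[int, float]
    shorter_length_distances: dict[int, float]
    length_independent: bool
    origin_cluster: int | None = None

    @property
    def min_same(self) -> float | None:
        return min(self.same_length_distances.values(), default=None)

    @property
    def min_shorter(self) -> float | None:
        return min(self.shorter_length_distances.values(), default=None)


def origin_cluster_match(
    novel: ClusterProfile,
    clusters_same_length: Sequence[ClusterProfile],
    clusters_shorter: Sequence[ClusterProfile],
    D_joint: DistanceMatrix,
) -> OriginMatchReport:
    """Medoid-to-medoid DTW comparison of a novel cluster across lengths.

    The cluster is flagged length-independent iff its closest shorter-length
    cluster is nearer than every cluster of its own length; the flag upgrades
    its novelty to LENGTH_INDEPENDENT_CANDIDATE and names the origin cluster.
    """
    same = {
        p.cluster_id: D_joint.distance(novel.medoid_id, p.medoid_id)
        for p in clusters_same_length
        if p.cluster_id != novel.cluster_id or p.medoid_id != novel.medoid_id
    }
    shorter = {
        p.cluster_id: D_joint.distance(novel.medoid_id, p.medoid_id)
        for p in clusters_shorter
    }
    if not shorter:
        return OriginMatchReport(novel.cluster_id, same, {}, False)

    min_shorter = min(shorter.values())
    min_same = min(same.values()) if same else np.inf
    flagged = min_shorter < min_same
    origin = None
    if flagged:
        origin = min(shorter, key=lambda c: (shorter[c], c))
        novel.novelty = Novelty.LENGTH_INDEPENDENT_CANDIDATE
    return OriginMatchReport(novel.cluster_id, same, shorter, flagged, origin)


@dataclass
class ShmSignatureReport:
    insertion_position: int | None
    match_fraction: float
    aligned_novel: str  # novel consensus with the inserted position removed
    no_flat_column: bool = False


def _match_fraction(a: str, b: str) -> float:
    """Fraction of identical consensus positions (case-insensitive)."""
    if len(a) != len(b):
        raise ValueError("consensus lengths differ after deletion")
    same = sum(1 for x, y in zip(a.lower(), b.lower()) if x == y)
    return same / len(b)


def shm_signature(novel: ClusterProfile, origin: ClusterProfile) -> ShmSignatureReport:
    """Sequence-level check that ``novel`` is a single insertion into ``origin``.

    Locates the flat logo column of the novel cluster, deletes it from the
    novel consensus and scores positional identity against the origin
    consensus.  Without a flat column, the best single-deletion alignment is
    reported and flagged.
    """
    if abs(novel.logo.length - origin.logo.length) != 1:
        raise ValueError(
            "origin cluster must be exactly one residue shorter than the novel cluster"
        )
    pos = insertion_position(novel.logo)
    consensus = novel.consensus
    if pos is not None:
        deleted = consensus[:pos] + consensus[pos + 1 :]
        return ShmSignatureReport(pos, _match_fraction(deleted, origin.consensus), deleted)
    best_frac, best_pos, best_del = -1.0, None, ""
    for p in range(len(consensus)):
        deleted = consensus[:p] + consensus[p + 1 :]
        frac = _match_fraction(deleted, origin.consensus)
        if frac > best_frac:
            best_frac, best_pos, best_del = frac, p, deleted
    return ShmSignatureReport(best_pos, best_frac, best_del, no_flat_column=True)
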