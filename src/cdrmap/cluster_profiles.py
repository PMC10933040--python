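"""Per-cluster characterization.

Each DBS cluster is profiled by its medoid (the member minimizing total
distance to the others, standing in for the cluster centroid), a bitwise
sequence logo (per-position residue frequencies and information content in
bits), a cased consensus motif in the canonical-form style (uppercase =
highly conserved, lowercase = less conserved, ``x`` = unconserved), a tally
of the canonical-form annotations of its experimental members, and a novelty
call separating known forms, subdivisions of a form, and novel candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AnnotationRecord
from .metrics import DistanceMatrix
from .types import EXPERIMENTAL, STANDARD_AA, UNASSIGNED, LoopRecord

MAX_BITS = math.log2(20.0)

#: Consensus case thresholds on the top-residue frequency.
UPPER_THRESHOLD = 0.75
LOWER_THRESHOLD = 0.35


class Novelty(str, Enum):
    KNOWN = "KNOWN"
    SUBDIVISION = "SUBDIVISION"
    NOVEL_CANDIDATE = "NOVEL_CANDIDATE"
    LENGTH_INDEPENDENT_CANDIDATE = "LENGTH_INDEPENDENT_CANDIDATE"

    def __str__(self) -> str:  # report-friendly
        return self.value


@dataclass
class LogoMatrix:
    """Position × residue frequencies with per-position information content."""

    frequencies: np.ndarray  # (length, 20), rows sum to 1
    information: np.ndarray  # (length,) bits in [0, log2 20]
    alphabet: str = STANDARD_AA

    @property
    def length(self) -> int:
        return self.frequencies.shape[0]

    def top_residue(self, position: int) -> tuple[str, float]:
        row = self.frequencies[position]
        idx = int(np.argmax(row))
        return self.alphabet[idx], float(row[idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.frequencies, columns=list(self.alphabet))
        df["information_bits"] = self.information
        df.index.name = "position"
        return df


@dataclass
class ClusterProfile:
    cluster_id: int
    size: int
    medoid_id: str
    logo: LogoMatrix
    consensus: str
    canonical_tally: dict[str, int] = field(default_factory=dict)
    unassigned_count: int = 0
    novelty: Novelty = Novelty.KNOWN
    member_ids: list[str] = field(default_factory=list)

    @property
    def n_experimental(self) -> int:
        return sum(self.canonical_tally.values()) + self.unassigned_count

    def majority_label(self) -> str | None:
        if not self.canonical_tally:
            return None
        return min(
            self.canonical_tally, key=lambda k: (-self.canonical_tally[k], k)
        )


def medoid(D: DistanceMatrix, members: Iterable[str]) -> str:
    """The member minimizing the sum of distances to all other members.

    Ties resolve to the lexicographically smallest loop ID.
    """
    members = sorted(members)
    if not members:
        raise ValueError("empty member set")
    idx = [D.index(m) for m in members]  # raises KeyError if absent
    sub = D.values[np.ix_(idx, idx)]
    sums = sub.sum(axis=1)
    return members[int(np.argmin(sums))]  # argmin takes first (smallest ID) tie


def centroid_distance(
    D: DistanceMatrix, members1: Iterable[str], members2: Iterable[str]
) -> float:
    """Distance between the medoids of two clusters in the same matrix."""
    return D.distance(medoid(D, members1), medoid(D, members2))


def logo_information(sequences: Sequence[str]) -> LogoMatrix:
    """Bitwise logo: frequencies and information = log2(20) − Shannon entropy.

    No small-sample correction is applied.
    """
    if not sequences:
        raise ValueError("no sequences")
    length = len(sequences[0])
    for seq in sequences:
        if len(seq) != length:
            raise ValueError(f"sequence {seq!r} has length {len(seq)} != {length}")
        bad = set(seq.upper()) - set(STANDARD_AA)
        if bad:
            raise ValueError(f"sequence {seq!r} has non-standard residues {bad}")
    counts = np.zeros((length, 20))
    index = {aa: i for i, aa in enumerate(STANDARD_AA)}
    for seq in sequences:
        for pos, aa in enumerate(seq.upper()):
            counts[pos, index[aa]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    information = np.clip(MAX_BITS - entropy, 0.0, MAX_BITS)
    return LogoMatrix(freqs, information)


def consensus_motif(
    logo: LogoMatrix,
    upper_t: float = UPPER_THRESHOLD,
    lower_t: float = LOWER_THRESHOLD,
) -> str:
    """Cased consensus: upper ≥ upper_t, lower ≥ lower_t, else 'x'."""
    out = []
    for pos in range(logo.length):
        aa, freq = logo.top_residue(pos)
        if freq >= upper_t:
            out.append(aa.upper())
        elif freq >= lower_t:
            out.append(aa.lower())
        else:
            out.append("x")
    return "".join(out)


def annotate_cluster(
    members: Sequence[LoopRecord],
    records: Mapping[str, AnnotationRecord] | None = None,
) -> tuple[dict[str, int], int]:
    """Tally high-confidence canonical labels of experimental members.

    Predicted members are ignored; unassigned experimental loops (label
    ending in '*') are counted separately.  When ``records`` is given it maps
    loop IDs to annotation rows; otherwise the loops' own ``annotation``
    fields are used.
    """
    tally: dict[str, int] = {}
    unassigned = 0
    for loop in members:
        if loop.source != EXPERIMENTAL:
            continue
        if records is not None:
            if loop.loop_id not in records:
                raise KeyError(
                    f"experimental loop {loop.loop_id!r} absent from annotation index"
                )
            label = records[loop.loop_id].cluster
        else:
            label = loop.annotation
        if label is None:
            raise KeyError(f"experimental loop {loop.loop_id!r} has no annotation")
        if label.endswith(UNASSIGNED):
            unassigned += 1
        else:
            tally[label] = tally.get(label, 0) + 1
    return tally, unassigned


def classify_novelty(
    profiles: Sequence[ClusterProfile],
    purity_t: float = 0.6,
    unassigned_t: float = 0.6,
) -> list[ClusterProfile]:
    """Set the novelty call on each profile (in place; returns the list).

    NOVEL_CANDIDATE: no experimental members, or the experimental members
    are mostly unassigned.  SUBDIVISION: two or more clusters share the same
    majority canonical label.  KNOWN: a single cluster holds its majority
    label.  LENGTH_INDEPENDENT_CANDIDATE is assigned later by the
    cross-length analysis and takes precedence over NOVEL_CANDIDATE.
    """
    majority: dict[int, str] = {}
    for prof in profiles:
        if prof.novelty == Novelty.LENGTH_INDEPENDENT_CANDIDATE:
            continue
        n_exp = prof.n_experimental
        if n_exp == 0 or prof.unassigned_count >= unassigned_t * n_exp:
            prof.novelty = Novelty.NOVEL_CANDIDATE
            continue
        label = prof.majority_label()
        if label is not None:
            majority[prof.cluster_id] = label
        prof.novelty = Novelty.KNOWN

    shared = {
        label
        for label in majority.values()
        if sum(1 for v in majority.values() if v == label) >= 2
    }
    for prof in profiles:
        if majority.get(prof.cluster_id) in shared:
            prof.novelty = Novelty.SUBDIVISION
    return list(profiles)


def insertion_position(
    logo: LogoMatrix, flat_t: float = 0.3, flank_t: float = 0.5
) -> int | None:
    """Interior position with no residue enrichment between conserved flanks.

    Such a flat column between conserved neighbours is the signature of a
    somatic-hypermutation insertion into a shorter conserved motif.  Returns
    the qualifying position with the lowest top-residue frequency, or None.
    """
    if logo.length < 3:
        raise ValueError("logo must have at least 3 positions")
    tops = np.array([logo.top_residue(p)[1] for p in range(logo.length)])
    best: int | None = None
    for pos in range(1, logo.length - 1):
        if tops[pos] < flat_t and tops[pos - 1] >= flank_t and tops[pos + 1] >= flank_t:
            if best is None or tops[pos] < tops[best]:
                best = pos
    return best


def build_profile(
    cluster_id: int,
    member_loops: Sequence[LoopRecord],
    D: DistanceMatrix,
    records: Mapping[str, AnnotationRecord] | None = None,
) -> ClusterProfile:
    """Assemble the full profile of one cluster."""
    ids = [lp.loop_id for lp in member_loops]
    logo = logo_information([lp.sequence for lp in member_loops])
    tally, unassigned = annotate_cluster(member_loops, records)
    return ClusterProfile(
        cluster_id=cluster_id,
        size=len(member_loops),
        medoid_id=medoid(D, ids),
        logo=logo,
        consensus=consensus_motif(logo),
        canonical_tally=tally,
        unassigned_count=unassigned,
        member_ids=ids,
    )
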