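"""Rigid superposition onto per-length templates.

Every chain in an analysis group is superposed onto a single template chosen
from the highest-resolution representative structure, by a least-squares
rigid fit of the alpha carbons at the ten framework anchor positions.  Fits
worse than 1.5 Å framework RMSD are rejected — a chain whose framework does
not match the template cannot be compared in a common frame.  Distances are
then computed in the template frame with no per-pair refitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .imgt_regions import anchor_positions
from .io_formats import AnnotationRecord
from .types import NumberedChain

#: Framework-fit rejection threshold in Å (strictly greater rejects).
FRAMEWORK_RMSD_CUTOFF = 1.5


@dataclass(frozen=True)
class RigidTransform:
    """x -> rotation @ x + translation, with a proper rotation."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


@dataclass
class TemplateChoice:
    structure_id: str
    chain_id: str
    resolution: float
    anchor_ca_coords: np.ndarray  # (10, 3)


@dataclass
class Rejection:
    """A chain excluded from the analysis, with the reason."""

    structure_id: str
    chain_id: str
    reason: str
    fit_rmsd: float | None = None


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit of ``mobile`` onto ``reference`` (SVD form).

    Returns the transform and the residual RMSD.  Reflections are rejected by
    the standard sign correction, so the rotation is always proper.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3) with equal n")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("at least 3 points are required for a rigid fit")

    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    x = mobile - mu_m
    y = reference - mu_r
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    # Degenerate (collinear) configurations leave the rotation underdetermined.
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = mu_r - rotation @ mu_m
    fitted = x @ rotation.T + mu_r
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return RigidTransform(rotation, translation), rmsd


def select_template(
    records: Sequence[AnnotationRecord],
    cdr: str,
    imgt_length: int,
    chains: dict[tuple[str, str], NumberedChain] | None = None,
) -> AnnotationRecord:
    """Pick the template record for one CDR/length group.

    The eligible records are complete (``cdr_ordered``) representatives of a
    canonical form for that CDR and length; the one with the numerically best
    resolution wins, ties broken by structure then chain ID.
    """
    eligible = [
        r
        for r in records
        if r.cdr == cdr
        and r.loop_length == imgt_length
        and r.is_representative
        and r.cdr_ordered
    ]
    if not eligible:
        raise ValueError(
            f"no representative, complete record for {cdr} length {imgt_length}; "
            "supply a template explicitly"
        )
    return min(eligible, key=lambda r: (r.resolution, r.structure_id, r.chain_id))


def template_from_chain(
    chain: NumberedChain, cdr: str, resolution: float
) -> TemplateChoice:
    """Build a TemplateChoice from the anchor CAs of a numbered chain."""
    coords = _anchor_cas(chain, cdr)
    if coords is None:
        raise ValueError(
            f"{chain.structure_id}/{chain.chain_id}: missing anchor CA atoms"
        )
    return TemplateChoice(chain.structure_id, chain.chain_id, resolution, coords)


def _anchor_cas(chain: NumberedChain, cdr: str) -> np.ndarray | None:
    coords = []
    for pos in anchor_positions(cdr):
        residue = chain.residue_at(pos)
        if residue is None or "CA" not in residue.atoms:
            return None
        coords.append(residue.atoms["CA"])
    return np.array(coords)


def align_chain_to_template(
    chain: NumberedChain, template: TemplateChoice, cdr: str
) -> NumberedChain | Rejection:
    """Superpose a whole chain onto the template via anchor-CA Kabsch fit.

    The entire chain is transformed so the loop can be extracted in template
    frame.  Returns a :class:`Rejection` when anchors are missing or the
    framework fit exceeds 1.5 Å (strictly greater; exactly 1.5 passes).
    """
    anchors = _anchor_cas(chain, cdr)
    if anchors is None:
        return Rejection(chain.structure_id, chain.chain_id, "incomplete framework")
    transform, rmsd = kabsch_superpose(anchors, template.anchor_ca_coords)
    if rmsd > FRAMEWORK_RMSD_CUTOFF:
        return Rejection(
            chain.structure_id,
            chain.chain_id,
            f"framework fit {rmsd:.3f} Å > {FRAMEWORK_RMSD_CUTOFF} Å",
            fit_rmsd=rmsd,
        )
    return chain.transformed(transform.rotation, transform.translation)
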