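"""Core in-memory containers shared across the pipeline.

A :class:`NumberedChain` is an antibody chain whose residues carry IMGT
position numbers verbatim from the input file; a :class:`LoopRecord` is one
CDR loop cut out of such a chain after superposition onto the per-length
template, holding only the N/CA/C backbone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Backbone atom order used everywhere (O is read but excluded from metrics).
BACKBONE_ATOMS = ("N", "CA", "C")

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Sentinel for loops not assigned to any high-confidence canonical form.
UNASSIGNED = "*"

EXPERIMENTAL = "experimental"
PREDICTED = "predicted"


@dataclass
class Residue:
    imgt_number: int
    amino_acid: str
    atoms: dict[str, np.ndarray]  # atom name -> (3,) coordinates in Å

    def has_backbone(self) -> bool:
        return all(name in self.atoms for name in BACKBONE_ATOMS)


@dataclass
class NumberedChain:
    """An ordered antibody chain with IMGT residue numbers.

    Residue numbers are taken verbatim from the source and must be strictly
    increasing; no renumbering is ever performed.
    """

    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    structure_id: str = ""

    def __post_init__(self) -> None:
        numbers = [r.imgt_number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValueError(
                f"chain {self.chain_id!r}: IMGT numbers not strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def residue_at(self, imgt_number: int) -> Residue | None:
        for r in self.residues:
            if r.imgt_number == imgt_number:
                return r
        return None

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "NumberedChain":
        """Return a copy with every atom mapped through x -> R x + t."""
        new_residues = [
            Residue(
                r.imgt_number,
                r.amino_acid,
                {name: rotation @ xyz + translation for name, xyz in r.atoms.items()},
            )
            for r in self.residues
        ]
        return NumberedChain(self.chain_id, new_residues, self.structure_id)


@dataclass
class LoopRecord:
    """One CDR loop in the template frame.

    ``backbone`` has shape (length, 3, 3): residues × (N, CA, C) × xyz.
    ``source`` is ``experimental`` or ``predicted``; ``annotation`` carries the
    canonical-form label of experimental loops when known ("*" = unassigned).
    """

    loop_id: str
    cdr: str  # L1, L2, L3, H1, H2, H3
    sequence: str
    imgt_numbers: list[int]
    backbone: np.ndarray
    source: str = PREDICTED
    annotation: str | None = None

    def __post_init__(self) -> None:
        self.backbone = np.asarray(self.backbone, dtype=float)
        if self.backbone.shape != (len(self.sequence), 3, 3):
            raise ValueError(
                f"loop {self.loop_id!r}: backbone shape {self.backbone.shape} "
                f"inconsistent with sequence length {len(self.sequence)}"
            )
        if len(self.imgt_numbers) != len(self.sequence):
            raise ValueError(f"loop {self.loop_id!r}: numbering/sequence length mismatch")

    @property
    def length(self) -> int:
        return len(self.sequence)
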