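"""Readers and writers for the formats the pipeline touches.

Structures come in as a restricted PDB dialect (ATOM/TER/END, single model,
no insertion codes) whose residue-sequence field is interpreted verbatim as
the IMGT position.  Loop annotations come in as a tab-delimited table in the
style of PyIgClassify2's ``pyig_cdr_data.txt``; the pipeline's own outputs are
tab-delimited reports plus per-cluster FASTA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

from .types import UNASSIGNED, LoopRecord, NumberedChain, Residue

if TYPE_CHECKING:  # pragma: no cover
    from .cluster_profiles import ClusterProfile
    from .dbs_clustering import ClusteringResult


class PdbParseError(ValueError):
    """Raised for ATOM records that cannot be interpreted, with line number."""


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_KEPT_ATOMS = ("N", "CA", "C", "O")


@dataclass
class AnnotationRecord:
    """One row of the per-loop annotation table.

    ``cluster`` holds the high-confidence canonical-form label; labels ending
    in ``*`` (e.g. ``L1-11-*``) mark loops unassigned to any high-confidence
    form.  ``cdr_ordered`` is False when the loop is missing backbone
    coordinates in the source structure and must be excluded from structural
    analysis; ``is_representative`` marks loops usable as superposition
    templates.
    """

    structure_id: str
    chain_id: str
    cdr: str
    loop_length: int
    sequence: str
    cluster: str
    cluster_nocutoff: str
    cdr_ordered: bool
    is_representative: bool
    resolution: float

    def __post_init__(self) -> None:
        if self.loop_length != len(self.sequence):
            raise ValueError(
                f"{self.structure_id}/{self.chain_id}/{self.cdr}: loop_length "
                f"{self.loop_length} != len(sequence) {len(self.sequence)}"
            )
        if not self.resolution > 0:
            raise ValueError(
                f"{self.structure_id}/{self.chain_id}/{self.cdr}: "
                f"resolution must be positive, got {self.resolution}"
            )

    @property
    def is_unassigned(self) -> bool:
        return self.cluster.endswith(UNASSIGNED)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.structure_id, self.chain_id, self.cdr)


# ---------------------------------------------------------------------------
# PDB subset
# ---------------------------------------------------------------------------

def read_pdb_chains(path: str | Path) -> list[NumberedChain]:
    """Parse a restricted PDB file into one :class:`NumberedChain` per chain.

    Only N/CA/C/O atoms are retained; alternate locations resolve to the
    first occurrence.  Insertion codes and duplicate residue numbers within a
    chain are errors (the dialect keeps IMGT numbering unambiguous).
    """
    path = Path(path)
    structure_id = path.stem
    chains: dict[str, list[Residue]] = {}
    order: list[str] = []
    seen_numbers: dict[str, set[int]] = {}
    current: tuple[str, int] | None = None  # (chain, resnum) being accumulated

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("ATOM"):
                current = current if not line.startswith("TER") else None
                continue
            if len(line.rstrip("\n")) < 54:
                raise PdbParseError(f"{path.name} line {lineno}: truncated ATOM record")
            try:
                atom_name = line[12:16].strip()
                altloc = line[16]
                resname = line[17:20].strip()
                chain_id = line[21].strip() or "_"
                resnum = int(line[22:26])
                icode = line[26]
                xyz = np.array(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
            except ValueError as exc:
                raise PdbParseError(
                    f"{path.name} line {lineno}: malformed ATOM record ({exc})"
                ) from None
            if icode.strip():
                raise PdbParseError(
                    f"{path.name} line {lineno}: insertion code {icode!r} not supported"
                )
            if atom_name not in _KEPT_ATOMS:
                continue
            if chain_id not in chains:
                chains[chain_id] = []
                order.append(chain_id)
                seen_numbers[chain_id] = set()
            residues = chains[chain_id]
            if current == (chain_id, resnum):
                residue = residues[-1]
                if atom_name in residue.atoms or (altloc.strip() and altloc != "A"):
                    continue  # first occurrence / first altloc wins
                residue.atoms[atom_name] = xyz
            else:
                if resnum in seen_numbers[chain_id]:
                    raise PdbParseError(
                        f"{path.name} line {lineno}: duplicate residue number "
                        f"{resnum} in chain {chain_id!r}"
                    )
                seen_numbers[chain_id].add(resnum)
                aa = THREE_TO_ONE.get(resname, "X")
                residues.append(Residue(resnum, aa, {atom_name: xyz}))
                current = (chain_id, resnum)

    return [
        NumberedChain(cid, chains[cid], structure_id=structure_id) for cid in order
    ]


def write_pdb(chain: NumberedChain, path: str | Path) -> None:
    """Write a chain as standard ATOM records (8.3 fixed-point coordinates)."""
    lines: list[str] = []
    serial = 1
    for residue in chain.residues:
        if residue.imgt_number > 9999:
            raise ValueError(
                f"residue number {residue.imgt_number} exceeds the PDB format limit"
            )
        resname = ONE_TO_THREE.get(residue.amino_acid, "UNK")
        for atom_name in _KEPT_ATOMS:
            if atom_name not in residue.atoms:
                continue
            x, y, z = residue.atoms[atom_name]
            lines.append(
                f"ATOM  {serial:5d} {atom_name:^4s} {resname:>3s} "
                f"{chain.chain_id[:1]:1s}{residue.imgt_number:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom_name[0]:>2s}"
            )
            serial += 1
    if chain.residues:
        lines.append(f"TER   {serial:5d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------

MANDATORY_COLUMNS = (
    "structure_id", "chain_id", "cdr", "loop_length", "sequence",
    "cluster", "cluster_nocutoff", "cdr_ordered", "is_representative",
    "resolution",
)

_TRUTHY = {"true", "t", "1", "yes", "y"}
_FALSY = {"false", "f", "0", "no", "n"}


def _parse_bool(value, column: str, row: int) -> bool:
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ValueError(f"row {row}: cannot parse boolean {column}={value!r}")


def read_annotation_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[AnnotationRecord]:
    """Read the tab-delimited per-loop annotation table.

    ``column_map`` maps the canonical field names to the headers actually
    present, for tables whose headers differ from the PyIgClassify2 names.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    rename = {v: k for k, v in (column_map or {}).items()}
    df = df.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {', '.join(missing)}")

    records: list[AnnotationRecord] = []
    for row_idx, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        try:
            length = int(row_d["loop_length"])
        except (TypeError, ValueError):
            raise ValueError(
                f"row {row_idx}: non-integer loop_length {row_d['loop_length']!r}"
            ) from None
        records.append(
            AnnotationRecord(
                structure_id=str(row_d["structure_id"]),
                chain_id=str(row_d["chain_id"]),
                cdr=str(row_d["cdr"]),
                loop_length=length,
                sequence=str(row_d["sequence"]),
                cluster=str(row_d["cluster"]),
                cluster_nocutoff=str(row_d["cluster_nocutoff"]),
                cdr_ordered=_parse_bool(row_d["cdr_ordered"], "cdr_ordered", row_idx),
                is_representative=_parse_bool(
                    row_d["is_representative"], "is_representative", row_idx
                ),
                resolution=float(row_d["resolution"]),
            )
        )
    return records


def write_annotation_table(records: Sequence[AnnotationRecord], path: str | Path) -> None:
    rows = [
        {col: getattr(r, col) for col in MANDATORY_COLUMNS} for r in records
    ]
    pd.DataFrame(rows, columns=list(MANDATORY_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Report + FASTA
# ---------------------------------------------------------------------------

def write_cluster_report(
    result: "ClusteringResult",
    profiles: Sequence["ClusterProfile"],
    path: str | Path,
    loops: Mapping[str, LoopRecord] | None = None,
    embedding=None,
) -> None:
    """Write the per-loop assignment table plus a per-cluster summary block.

    One row per loop (loop ID, cluster label, source class, canonical
    annotation, MDS coordinates when an embedding is supplied), then comment
    rows summarising each cluster (size, medoid, consensus motif, novelty).
    """
    coords = {}
    if embedding is not None:
        coords = {i: c for i, c in zip(embedding.ids, embedding.coords)}
    header = ["loop_id", "cluster", "source", "annotation", "MDS1", "MDS2"]
    lines = ["\t".join(header)]
    for loop_id, label in zip(result.ids, result.labels):
        loop = loops.get(loop_id) if loops else None
        xy = coords.get(loop_id)
        lines.append(
            "\t".join(
                [
                    loop_id,
                    str(label),
                    loop.source if loop else "",
                    (loop.annotation or "") if loop else "",
                    f"{xy[0]:.4f}" if xy is not None else "",
                    f"{xy[1]:.4f}" if xy is not None else "",
                ]
            )
        )
    for prof in profiles:
        lines.append(
            "\t".join(
                [
                    f"#cluster\t{prof.cluster_id}",
                    f"size={prof.size}",
                    f"medoid={prof.medoid_id}",
                    f"consensus={prof.consensus}",
                    f"novelty={prof.novelty}",
                    f"unassigned={prof.unassigned_count}",
                    "tally=" + ";".join(
                        f"{k}:{v}" for k, v in sorted(prof.canonical_tally.items())
                    ),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(
    entries: Iterable[tuple[str, str]], path: str | Path, width: int = 60
) -> None:
    """Write ``(identifier, sequence)`` pairs as FASTA (ID = loopID|cluster)."""
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_distance_matrix(matrix, path: str | Path) -> None:
    """Persist a distance matrix as TSV with an ID header row/column."""
    df = pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids)
    df.to_csv(path, sep="\t", index_label=f"#metric={matrix.metric}")


def read_distance_matrix(path: str | Path):
    from .metrics import DistanceMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    metric = df.index.name.split("=", 1)[1] if "=" in str(df.index.name) else "RMSD"
    return DistanceMatrix(
        ids=list(df.columns), values=df.to_numpy(dtype=float), metric=metric
    )
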