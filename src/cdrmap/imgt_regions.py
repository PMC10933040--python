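"""IMGT region arithmetic.

Fixed IMGT CDR ranges (CDR1: 27-38, CDR2: 56-65, CDR3: 105-117), the ten
framework anchor positions flanking each CDR, loop extraction from numbered
chains, the chain validity checks applied before structural analysis, and the
literal IMGT-to-AHo loop-length lookup.

IMGT places loop insertions at fixed central positions, so a loop shorter
than its range is represented purely by which positions are occupied; this
module never re-derives gap placement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .types import LoopRecord, NumberedChain

#: Inclusive IMGT position intervals per CDR.
CDR_RANGES: dict[str, tuple[int, int]] = {
    "CDR1": (27, 38),
    "CDR2": (56, 65),
    "CDR3": (105, 117),
}

#: Five framework positions either side of each CDR (alpha-carbon anchors).
ANCHOR_FLANKS: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "CDR1": ((22, 26), (39, 43)),
    "CDR2": ((51, 55), (66, 70)),
    "CDR3": ((100, 104), (118, 122)),
}

#: Chain-specific CDR names (L1, H2, ...) map onto the generic CDR index.
_CHAIN_CDRS = {f"{c}{i}": f"CDR{i}" for c in "LH" for i in (1, 2, 3)}

# Chain validity thresholds: variable-domain chains must span the full IMGT
# numbering to guarantee anchors and CDRs are present.
MIN_RESIDUES = 70
MAX_START_NUMBER = 8  # first IMGT number must be < 8
MIN_END_NUMBER = 120  # last IMGT number must be > 120


@dataclass(frozen=True)
class CdrDefinition:
    cdr: str
    range: tuple[int, int]
    anchors: tuple[int, ...]


class IncompleteLoopError(ValueError):
    """A residue inside the CDR range is missing a backbone atom."""


class AhoLookupError(KeyError):
    """The (CDR, IMGT length) pair is not in the lookup; never extrapolated."""


def _generic(cdr: str) -> str:
    if cdr in CDR_RANGES:
        return cdr
    if cdr in _CHAIN_CDRS:
        return _CHAIN_CDRS[cdr]
    raise ValueError(f"unknown CDR {cdr!r}")


def cdr_range(cdr: str) -> tuple[int, int]:
    """Inclusive IMGT interval of a CDR; accepts CDR1/CDR2/CDR3 or L1...H3."""
    return CDR_RANGES[_generic(cdr)]


def anchor_positions(cdr: str) -> list[int]:
    """The ten framework anchor positions, ascending (5 before, 5 after)."""
    (a0, a1), (b0, b1) = ANCHOR_FLANKS[_generic(cdr)]
    return list(range(a0, a1 + 1)) + list(range(b0, b1 + 1))


def cdr_definition(cdr: str) -> CdrDefinition:
    g = _generic(cdr)
    return CdrDefinition(g, CDR_RANGES[g], tuple(anchor_positions(g)))


def extract_cdr_loop(
    chain: NumberedChain,
    cdr: str,
    loop_id: str | None = None,
    source: str = "predicted",
    annotation: str | None = None,
) -> LoopRecord:
    """Cut the CDR loop out of a (template-frame) chain as a LoopRecord.

    Length is the count of occupied positions inside the CDR range; a missing
    N/CA/C atom raises :class:`IncompleteLoopError` so the caller can exclude
    the loop, mirroring the completeness (``cdr_ordered``) filter.
    """
    lo, hi = cdr_range(cdr)
    residues = [r for r in chain.residues if lo <= r.imgt_number <= hi]
    for r in residues:
        if not r.has_backbone():
            raise IncompleteLoopError(
                f"{chain.structure_id}/{chain.chain_id} {cdr}: residue "
                f"{r.imgt_number} is missing a backbone atom"
            )
    import numpy as np

    backbone = np.array(
        [[r.atoms[a] for a in ("N", "CA", "C")] for r in residues]
    ).reshape(len(residues), 3, 3)
    return LoopRecord(
        loop_id=loop_id or f"{chain.structure_id}_{chain.chain_id}_{cdr}",
        cdr=cdr if cdr in _CHAIN_CDRS else _generic(cdr),
        sequence="".join(r.amino_acid for r in residues),
        imgt_numbers=[r.imgt_number for r in residues],
        backbone=backbone,
        source=source,
        annotation=annotation,
    )


def validate_chain(chain: NumberedChain) -> list[str]:
    """Return the list of violated validity rules (empty = pass).

    A chain passes when it has at least 70 residues, starts before IMGT
    position 8 and ends after position 120 — the checks applied to paired
    sequences before structure prediction.
    """
    failures: list[str] = []
    if len(chain) < MIN_RESIDUES:
        failures.append(f"fewer than {MIN_RESIDUES} residues ({len(chain)})")
    first = chain.residues[0].imgt_number if chain.residues else None
    last = chain.residues[-1].imgt_number if chain.residues else None
    if first is None or first >= MAX_START_NUMBER:
        failures.append(f"starting IMGT number not < {MAX_START_NUMBER} ({first})")
    if last is None or last <= MIN_END_NUMBER:
        failures.append(f"end IMGT number not > {MIN_END_NUMBER} ({last})")
    return failures


# ---------------------------------------------------------------------------
# IMGT <-> AHo length lookup
# ---------------------------------------------------------------------------

def _load_aho_table() -> dict[tuple[str, int], int]:
    with resources.files("cdrmap.data").joinpath("aho_lengths.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return {
        (str(row.cdr), int(row.imgt_length)): int(row.aho_length)
        for row in df.itertuples(index=False)
    }


_AHO_TABLE: dict[tuple[str, int], int] | None = None

# The printed H2 row maps IMGT length 10 to AHo 11 while its only form is
# named H2-12-1 (implying AHo 12); the printed value is stored and flagged.
_INCONSISTENT_KEYS = {("H2", 10)}


def imgt_to_aho_length(cdr_key: str, imgt_length: int) -> int:
    """AHo loop length for a (chain-specific CDR, IMGT length) pair.

    A literal lookup over the 17 analysed CDR/length combinations; unknown
    pairs raise :class:`AhoLookupError` rather than extrapolating (the
    IMGT/AHo offset differs per CDR and is not a fixed rule).
    """
    global _AHO_TABLE
    if _AHO_TABLE is None:
        _AHO_TABLE = _load_aho_table()
    key = (cdr_key, imgt_length)
    if key not in _AHO_TABLE:
        raise AhoLookupError(
            f"no AHo length recorded for {cdr_key} at IMGT length {imgt_length}"
        )
    if key in _INCONSISTENT_KEYS:
        warnings.warn(
            f"AHo length for {cdr_key}/{imgt_length} is internally inconsistent "
            "in the reference classification (form name implies a different "
            "length); returning the recorded value",
            stacklevel=2,
        )
    return _AHO_TABLE[key]


def aho_table() -> dict[tuple[str, int], int]:
    """The full lookup as a dict (copy)."""
    global _AHO_TABLE
    if _AHO_TABLE is None:
        _AHO_TABLE = _load_aho_table()
    return dict(_AHO_TABLE)
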