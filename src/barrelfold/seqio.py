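"""Sequence and annotation I/O, core domain types, and the hydropathy scale.

Residue coordinates are 1-based inclusive throughout the package, matching
the convention used for strand intervals everywhere downstream.  Conversion
to 0-based half-open happens only inside I/O helpers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "STANDARD_RESIDUES",
    "KYTE_DOOLITTLE",
    "ProteinSequence",
    "LabeledStructure",
    "hydropathy",
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "write_annotation",
    "strands_from_states",
    "states_from_strands",
]

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Kyte-Doolittle hydropathy index, the scale used for every hydrophobicity
#: term in the package.  Higher means more hydrophobic.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


def hydropathy(residue: str, strict: bool = False) -> float:
    """Kyte-Doolittle hydropathy of a one-letter residue code.

    Non-standard codes (B, Z, X, U, ...) default to a neutral 0.0 with a
    warning, so that screening real-world FASTA never crashes; pass
    ``strict=True`` to raise instead.
    """
    try:
        return KYTE_DOOLITTLE[residue]
    except KeyError:
        if strict:
            raise ValueError(f"unknown residue code {residue!r}")
        warnings.warn(f"non-standard residue {residue!r}: hydropathy set to 0.0",
                      stacklevel=2)
        return 0.0


@dataclass(frozen=True)
class ProteinSequence:
    """A primary structure: identifier plus residue string, positions 1..N."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("empty sequence")
        object.__setattr__(self, "residues", self.residues.upper())
        unknown = set(self.residues) - STANDARD_RESIDUES
        if unknown:
            warnings.warn(
                f"sequence {self.id}: non-standard residues {sorted(unknown)}",
                stacklevel=2)

    @property
    def n(self) -> int:
        return len(self.residues)

    def residue(self, position: int) -> str:
        """Residue at 1-based position."""
        if not 1 <= position <= self.n:
            raise IndexError(f"position {position} outside 1..{self.n}")
        return self.residues[position - 1]

    def segment(self, start: int, end: int) -> str:
        """Substring for the 1-based inclusive interval [start, end]."""
        if not 1 <= start <= end <= self.n:
            raise IndexError(f"bad interval ({start},{end}) for N={self.n}")
        return self.residues[start - 1:end]


def strands_from_states(states: str) -> list[tuple[int, int]]:
    """Maximal runs of 'S' in a state string, as 1-based inclusive intervals."""
    strands: list[tuple[int, int]] = []
    start = None
    for pos, st in enumerate(states, start=1):
        if st == "S" and start is None:
            start = pos
        elif st != "S" and start is not None:
            strands.append((start, pos - 1))
            start = None
    if start is not None:
        strands.append((start, len(states)))
    return strands


def states_from_strands(n: int, strands: Iterable[tuple[int, int]]) -> str:
    """Inverse of :func:`strands_from_states`: 'S'/'L' string of length n."""
    out = ["L"] * n
    for start, end in strands:
        if not 1 <= start <= end <= n:
            raise ValueError(f"strand ({start},{end}) outside 1..{n}")
        for p in range(start - 1, end):
            out[p] = "S"
    return "".join(out)


@dataclass(frozen=True)
class LabeledStructure:
    """A sequence with a per-residue two-state annotation (strand / other).

    ``states`` is a string over {'S', 'L'} of the same length as the
    sequence; ``strands`` is derived as the maximal 'S'-runs.
    """

    sequence: ProteinSequence
    states: str
    strands: tuple[tuple[int, int], ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.states) != self.sequence.n:
            raise ValueError(
                f"states length {len(self.states)} != sequence length "
                f"{self.sequence.n}")
        bad = set(self.states) - {"S", "L"}
        if bad:
            raise ValueError(f"state alphabet is {{S, L}}; found {sorted(bad)}")
        object.__setattr__(self, "strands",
                           tuple(strands_from_states(self.states)))


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a (possibly multi-record, line-wrapped) FASTA file.

    The header token before the first whitespace becomes the id.  An empty
    file yields an empty list.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinSequence(id=rec.id, residues=str(rec.seq)))
    return records


def write_fasta(sequences: Sequence[ProteinSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, seq.n, 60):
                fh.write(seq.residues[i:i + 60] + "\n")


def read_annotation(path: str | Path) -> list[LabeledStructure]:
    """Read the paired annotation format.

    Each record is three lines: a FASTA-style ``>id`` header, the residue
    line, and a state line over {S, L} of equal length.
    """
    out: list[LabeledStructure] = []
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()
             if ln.strip()]
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            raise ValueError(f"expected '>' header at line {i + 1}: {header!r}")
        if i + 2 >= len(lines):
            raise ValueError(f"truncated record for {header!r}")
        seq_line, state_line = lines[i + 1], lines[i + 2]
        if len(seq_line) != len(state_line):
            raise ValueError(
                f"record {header!r}: sequence length {len(seq_line)} != "
                f"state length {len(state_line)}")
        ident = header[1:].split()[0] if len(header) > 1 else "unnamed"
        out.append(LabeledStructure(
            sequence=ProteinSequence(id=ident, residues=seq_line),
            states=state_line.upper()))
        i += 3
    return out


def write_annotation(structures: Sequence[LabeledStructure],
                     path: str | Path) -> None:
    with open(path, "w") as fh:
        for st in structures:
            fh.write(f">{st.sequence.id}\n{st.sequence.residues}\n{st.states}\n")
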