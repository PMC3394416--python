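"""Membrane-spanning strand candidate filter.

Two independent tests are combined.  The *amphipathicity* test splits a
segment into its two faces (even- and odd-indexed residues: a beta-strand
alternates side chains between the lipid bilayer and the channel) and
requires one face to be hydrophobic and the other hydrophilic.  The
*block-information* test scores the segment with log-odds preferences of
short residue blocks for the strand conformation, learned from a labeled
training set.

The block statistic for a segment r_1..r_p with block length l is

    I~(tau:tau_bar; r_1..r_p)
        = sum_{i=1}^{p-l+1} I(tau:tau_bar; r_i..r_{i+l-1}) - (p-l+1) log rho

with I(tau:tau_bar; r) = log[(f_{tau,r}/f_{tau,.}) / (f_{tau_bar,r}/f_{tau_bar,.})],
and the segment is a candidate for conformation tau when the statistic is
positive.  Natural logarithms are used; only the sign of the statistic
matters for acceptance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .config import RunConfig
from .seqio import LabeledStructure, ProteinSequence, hydropathy

__all__ = [
    "STRAND",
    "OTHER",
    "BlockFrequencyTable",
    "SegmentCandidate",
    "train_block_table",
    "side_averages",
    "candidate_segments",
]

STRAND = "strand"
OTHER = "other"
_CONFORMATIONS = (STRAND, OTHER)

Facing = Literal["odd_inward", "odd_outward"]


class BlockFrequencyTable:
    """Observed frequencies f_{tau,r} of l-residue blocks per conformation.

    Laplace smoothing over the 20^l block space is applied lazily: a queried
    cell returns its raw count plus the pseudocount, and the marginals
    account for the full smoothed mass, so the marginal identities hold
    exactly and — for any positive pseudocount — every logarithm is finite.
    A zero pseudocount is allowed for fully specified tables.
    """

    #: size of the standard residue alphabet backing the 20^l block space
    ALPHABET_SIZE = 20

    def __init__(self, block_len: int, pseudocount: float = 1.0) -> None:
        if block_len < 1:
            raise ValueError("block length must be >= 1")
        if pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        self.l = block_len
        self.pseudocount = pseudocount
        self._counts: dict[str, dict[str, float]] = {c: {} for c in _CONFORMATIONS}
        self._raw_totals: dict[str, float] = {c: 0.0 for c in _CONFORMATIONS}

    # -- accounting ---------------------------------------------------------

    @property
    def n_blocks(self) -> int:
        return self.ALPHABET_SIZE ** self.l

    def add(self, conformation: str, block: str, count: float = 1.0) -> None:
        if conformation not in _CONFORMATIONS:
            raise ValueError(f"unknown conformation {conformation!r}")
        if len(block) != self.l:
            raise ValueError(f"block {block!r} is not length {self.l}")
        cell = self._counts[conformation]
        cell[block] = cell.get(block, 0.0) + count
        self._raw_totals[conformation] += count

    def f(self, conformation: str, block: str) -> float:
        """Smoothed cell f_{tau,r}."""
        return self._counts[conformation].get(block, 0.0) + self.pseudocount

    def f_block(self, block: str) -> float:
        """Smoothed column marginal f_{.,r}."""
        return sum(self.f(c, block) for c in _CONFORMATIONS)

    def f_conformation(self, conformation: str) -> float:
        """Smoothed row marginal f_{tau,.} over the 20^l block space."""
        return (self._raw_totals[conformation]
                + self.pseudocount * self.n_blocks)

    def f_total(self) -> float:
        """Smoothed grand total f_{.,.}."""
        return sum(self.f_conformation(c) for c in _CONFORMATIONS)

    # -- information scores -------------------------------------------------

    def block_info(self, conformation: str, block: str) -> float:
        """I(tau; r) = log[(f_{tau,r}/f_{.,r}) * (f_{.,.}/f_{tau,.})]."""
        return math.log(
            (self.f(conformation, block) / self.f_block(block))
            * (self.f_total() / self.f_conformation(conformation)))

    def block_preference(self, block: str, conformation: str = STRAND) -> float:
        """I(tau:tau_bar; r), the preference of r for tau over its complement.

        Antisymmetric in (tau, tau_bar).
        """
        other = OTHER if conformation == STRAND else STRAND
        return math.log(
            (self.f(conformation, block) / self.f_conformation(conformation))
            / (self.f(other, block) / self.f_conformation(other)))

    def segment_score(self, segment: str, rho: float,
                      conformation: str = STRAND) -> float:
        """Summed block preference of a segment, offset by -(p-l+1) log rho.

        The segment is a candidate for ``conformation`` when the returned
        value is positive.
        """
        p, l = len(segment), self.l
        if p < l:
            raise ValueError(f"segment length {p} < block length {l}")
        n_blocks = p - l + 1
        total = sum(self.block_preference(segment[i:i + l], conformation)
                    for i in range(n_blocks))
        return total - n_blocks * math.log(rho)

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write as TSV (conformation, block, raw count) with an l header."""
        with open(path, "w") as fh:
            fh.write(f"#l\t{self.l}\n#pseudocount\t{self.pseudocount}\n")
            for conf in _CONFORMATIONS:
                for block in sorted(self._counts[conf]):
                    fh.write(f"{conf}\t{block}\t{self._counts[conf][block]}\n")

    @classmethod
    def load(cls, path: str | Path) -> "BlockFrequencyTable":
        l = None
        pseudocount = 1.0
        rows = []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            if line.startswith("#l\t"):
                l = int(line.split("\t")[1])
            elif line.startswith("#pseudocount\t"):
                pseudocount = float(line.split("\t")[1])
            else:
                conf, block, count = line.split("\t")
                rows.append((conf, block, float(count)))
        if l is None:
            raise ValueError("missing #l header")
        table = cls(l, pseudocount)
        for conf, block, count in rows:
            table.add(conf, block, count)
        return table


def train_block_table(training: Sequence[LabeledStructure], block_len: int = 3,
                      pseudocount: float = 0.1) -> BlockFrequencyTable:
    """Count length-l windows lying fully inside one conformation run.

    Windows straddling a strand/loop boundary are not counted for either
    conformation.
    """
    if not training:
        raise ValueError("empty training set")
    table = BlockFrequencyTable(block_len, pseudocount)
    for item in training:
        seq, states = item.sequence.residues, item.states
        for i in range(len(seq) - block_len + 1):
            window_states = states[i:i + block_len]
            if window_states == "S" * block_len:
                table.add(STRAND, seq[i:i + block_len])
            elif "S" not in window_states:
                table.add(OTHER, seq[i:i + block_len])
    return table


def side_averages(seq: ProteinSequence, start: int, end: int) -> tuple[float, float]:
    """(H_even, H_odd): mean hydropathy over even/odd absolute positions.

    Parity refers to the absolute 1-based sequence position, so shifting a
    segment by one residue swaps which physical face is "odd".
    """
    if not 1 <= start <= end <= seq.n:
        raise IndexError(f"bad interval ({start},{end})")
    evens = [hydropathy(seq.residue(p)) for p in range(start, end + 1) if p % 2 == 0]
    odds = [hydropathy(seq.residue(p)) for p in range(start, end + 1) if p % 2 == 1]
    if not evens or not odds:
        raise ValueError("segment too short to have both parities")
    return sum(evens) / len(evens), sum(odds) / len(odds)


@dataclass(frozen=True)
class SegmentCandidate:
    """A substring passing both filters, annotated with facing and score."""

    start: int
    end: int
    facing: Facing
    h_even: float
    h_odd: float
    score: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def candidate_segments(seq: ProteinSequence, table: BlockFrequencyTable,
                       config: RunConfig | None = None) -> list[SegmentCandidate]:
    """All intervals that can be membrane-spanning beta-strands.

    An interval qualifies when its length lies in ``strand_len_bounds``, the
    two side averages satisfy max > zeta_minus and min < zeta_plus, and the
    block statistic for the strand conformation is positive at threshold
    rho.  Facing is set by which parity is the more hydrophobic; an exact
    tie emits both facings (the graph downstream resolves ties by energy).
    Output is sorted by (start, end).
    """
    config = config or RunConfig()
    lo, hi = config.strand_len_bounds
    out: list[SegmentCandidate] = []
    for start in range(1, seq.n + 1):
        for length in range(lo, hi + 1):
            end = start + length - 1
            if end > seq.n:
                break
            h_even, h_odd = side_averages(seq, start, end)
            if max(h_even, h_odd) <= config.zeta_minus:
                continue
            if min(h_even, h_odd) >= config.zeta_plus:
                continue
            score = table.segment_score(seq.segment(start, end), config.rho,
                                        STRAND)
            if score <= 0:
                continue
            if h_odd < h_even:
                facings: Iterable[Facing] = ("odd_inward",)
            elif h_even < h_odd:
                facings = ("odd_outward",)
            else:
                facings = ("odd_inward", "odd_outward")
            for facing in facings:
                out.append(SegmentCandidate(start, end, facing, h_even, h_odd,
                                            score))
    out.sort(key=lambda c: (c.start, c.end, c.facing))
    return out
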