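"""Deterministic synthetic data: amphipathic barrel sequences and test graphs.

These generators emulate the amphipathic signature of membrane-spanning
strands — side chains alternating between a hydrophobic (lipid-contacting)
and a hydrophilic (channel-lining) face — separated by short flexible
loops.  They provide planted ground truth for every other module without
any external data: labeled training sets for the block filter, sequences
with known strand intervals for end-to-end recovery, and small random fold
graphs for exhaustive oracle testing of the dynamic programs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace

from .config import RunConfig
from .graph import FoldGraph, StrandCandidate, TableEnergyModel
from .seqio import LabeledStructure, ProteinSequence

__all__ = ["FixtureSpec", "make_barrel_fixture", "make_training_set",
           "make_random_graph"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic barrel sequence.

    The planted geometry is an n-strand barrel with uniform relative shear
    1, i.e. shear number S = n_strands.
    """

    n_strands: int = 8
    strand_len: int = 10
    loop_len: int = 4
    termini: int = 5
    seed: int = 0
    hydrophobic: tuple[str, ...] = ("I", "L", "V", "F")
    hydrophilic: tuple[str, ...] = ("D", "E", "N", "Q")
    loop_alphabet: tuple[str, ...] = ("G", "S", "P")

    def __post_init__(self) -> None:
        if self.n_strands < 2 or self.strand_len < 2 or self.loop_len < 2:
            raise ValueError("degenerate fixture dimensions")
        if set(self.hydrophobic) & set(self.hydrophilic):
            raise ValueError("face alphabets must be disjoint")

    @property
    def planted_S(self) -> int:
        return self.n_strands


def make_barrel_fixture(spec: FixtureSpec) -> LabeledStructure:
    """A synthetic amphipathic barrel sequence with per-residue labels.

    Strand residues alternate hydrophobic/hydrophilic starting hydrophobic,
    so each strand's two absolute-parity faces are cleanly separated; loops
    and termini draw from the flexible hydrophilic loop alphabet.
    Bit-reproducible for a given (spec, seed).
    """
    rng = random.Random(spec.seed)
    residues: list[str] = []
    states: list[str] = []

    def emit_loop(length: int) -> None:
        for _ in range(length):
            residues.append(rng.choice(spec.loop_alphabet))
            states.append("L")

    emit_loop(spec.termini)
    for strand in range(spec.n_strands):
        if strand > 0:
            emit_loop(spec.loop_len)
        for offset in range(spec.strand_len):
            alphabet = spec.hydrophobic if offset % 2 == 0 else spec.hydrophilic
            residues.append(rng.choice(alphabet))
            states.append("S")
    emit_loop(spec.termini)
    seq = ProteinSequence(id=f"fixture-{spec.n_strands}x{spec.strand_len}"
                             f"-seed{spec.seed}",
                          residues="".join(residues))
    return LabeledStructure(sequence=seq, states="".join(states))


def make_training_set(count: int, spec: FixtureSpec | None = None,
                      seed: int = 0) -> list[LabeledStructure]:
    """Independent fixtures with varied dimensions, for filter training."""
    if count < 1:
        raise ValueError("count must be >= 1")
    base = spec or FixtureSpec()
    rng = random.Random(seed)
    out = []
    for _ in range(count):
        item = replace(base,
                       n_strands=rng.choice((8, 10, 12)),
                       strand_len=rng.randint(8, 12),
                       loop_len=rng.randint(3, 6),
                       seed=rng.randrange(2 ** 31))
        out.append(make_barrel_fixture(item))
    return out


def make_random_graph(num_vertices: int, seed: int = 0,
                      config: RunConfig | None = None,
                      edge_prob: float = 0.9) -> FoldGraph:
    """A small random fold graph with table-backed energies.

    Vertex intervals are laid out left to right with turn-compatible gaps,
    directions alternate with canonical rank (so antiparallel paths exist),
    and all energies are random table entries.  Deterministic under seed;
    intended as the substrate for exhaustive DP-versus-oracle tests.
    """
    if num_vertices > 16:
        raise ValueError("random graphs are capped at 16 vertices")
    config = config or RunConfig()
    rng = random.Random(seed)
    vertices: list[StrandCandidate] = []
    position = rng.randint(1, 5)
    for i in range(num_vertices):
        length = rng.randint(6, 10)
        vertices.append(StrandCandidate(
            nu=position, kappa=position + length - 1,
            direction="up" if i % 2 == 0 else "down",
            facing=rng.choice(("odd_inward", "odd_outward"))))
        position += length + rng.randint(3, 8)

    successors: dict[int, list[int]] = {i: [] for i in range(num_vertices)}
    for i, v in enumerate(vertices):
        for j, w in enumerate(vertices):
            if v.kappa < w.nu - 2 and rng.random() < edge_prob:
                successors[i].append(j)

    grid = list(config.shear_grid())
    intr = {i: rng.uniform(-5.0, 0.0) for i in range(num_vertices)}
    adj: dict[tuple[int, int], dict[int, float]] = {}
    for i in range(num_vertices):
        for j in range(num_vertices):
            if i != j:
                adj[(i, j)] = {s: rng.uniform(-10.0, 0.0) for s in grid}
    loop = {(i, j, t): rng.uniform(0.0, 2.0)
            for i in range(num_vertices) for j in range(num_vertices)
            for t in range(1, max(2, num_vertices)) if i != j}
    loop_top = {i: rng.uniform(0.0, 1.0) for i in range(num_vertices)}
    loop_bottom = {i: rng.uniform(0.0, 1.0) for i in range(num_vertices)}
    energy = TableEnergyModel(intr, adj, loop, loop_top, loop_bottom)
    return FoldGraph(vertices, successors,
                     start_ok=set(range(num_vertices)),
                     end_ok=set(range(num_vertices)),
                     energy=energy, config=config)
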