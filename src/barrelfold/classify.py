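"""TMB recognition, permutation landscape scans, and loop mutagenesis.

A sequence is accepted as a transmembrane beta-barrel when the energy
minimization framework can close a barrel at all, and the resulting
per-strand criterion C/n clears a threshold; sequences whose filter yields
too few strand candidates, or that cannot satisfy any (n, S) couple, are
rejected.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .config import RunConfig
from .filter import BlockFrequencyTable
from .geometry import enumerate_nS
from .graph import FoldGraph, build_graph
from .seqio import (LabeledStructure, ProteinSequence, states_from_strands)
from .solver import (BarrelPermutation, BarrelStructure, fold_barrel_permuted,
                     fold_barrel_scan)

__all__ = ["ClassificationResult", "classify", "permutation_landscape",
           "mutate_loops", "structure_to_labeled", "write_structure"]


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of a TMB/non-TMB decision."""

    decision: str  # "TMB" | "non-TMB"
    best_structure: BarrelStructure | None
    per_strand_criterion: float | None
    scanned: tuple[tuple[int, int, float | None], ...]  # (n, S, criterion)

    @property
    def is_tmb(self) -> bool:
        return self.decision == "TMB"


def structure_to_labeled(structure: BarrelStructure,
                         seq: ProteinSequence) -> LabeledStructure:
    """Per-residue {S, L} annotation implied by a solved structure."""
    states = states_from_strands(seq.n, structure.strand_intervals())
    return LabeledStructure(sequence=seq, states=states)


def classify(seq: ProteinSequence, table: BlockFrequencyTable,
             config: RunConfig | None = None,
             exhaustive_shear: bool = True) -> ClassificationResult:
    """Scan all admissible (n, S) couples and decide TMB / non-TMB.

    The barrel solver runs in exhaustive-shear mode by default here: when S
    is being scanned rather than known, per-pair optimal shears almost
    never sum to the S under test, so the branching mode is what makes the
    scan meaningful.
    """
    config = config or RunConfig()
    couples = enumerate_nS(seq.n, config)
    if not couples:
        return ClassificationResult("non-TMB", None, None, ())
    graph = build_graph(seq, table, config)
    scanned: list[tuple[int, int, float | None]] = []
    best: BarrelStructure | None = None
    for n in sorted({n for n, _ in couples}):
        s_values = [S for m, S in couples if m == n]
        if graph.n_vertices < 2 * n:  # < n strands even before placement
            scanned.extend((n, S, None) for S in s_values)
            continue
        results = fold_barrel_scan(graph, n, s_values, exhaustive_shear)
        for S in s_values:
            structure = results[S]
            scanned.append((n, S, None if structure is None
                            else structure.criterion))
            if structure is not None and (
                    best is None or structure.criterion > best.criterion):
                best = structure
    if best is None:
        return ClassificationResult("non-TMB", None, None, tuple(scanned))
    per_strand = best.per_strand_criterion
    decision = "TMB" if per_strand >= config.classify_threshold else "non-TMB"
    return ClassificationResult(decision, best, per_strand, tuple(scanned))


def permutation_landscape(graph: FoldGraph, n: int, S: int,
                          permutations: Iterable[BarrelPermutation],
                          energy_window: float | None = None,
                          exhaustive_shear: bool = False
                          ) -> tuple[list[tuple[BarrelPermutation, float | None]],
                                     list[tuple[BarrelPermutation, float]]]:
    """Energy per permutation, plus the low-energy set within a window.

    Returns (rows, low): one row per supplied permutation with its optimal
    energy (None if infeasible), and the feasible permutations whose energy
    lies within ``energy_window`` (relative) of the minimum.  A window of 0
    keeps only the global minimizer(s).
    """
    rows: list[tuple[BarrelPermutation, float | None]] = []
    for sigma in permutations:
        structure = fold_barrel_permuted(graph, n, S, sigma,
                                         exhaustive_shear=exhaustive_shear)
        rows.append((sigma, None if structure is None else structure.energy))
    window = (graph.config.energy_window if energy_window is None
              else energy_window)
    feasible = [(sig, e) for sig, e in rows if e is not None]
    if not feasible:
        return rows, []
    e_min = min(e for _sig, e in feasible)
    cutoff = e_min + abs(e_min) * window
    low = [(sig, e) for sig, e in feasible if e <= cutoff]
    return rows, low


def _pam250_weights() -> dict[str, list[tuple[str, float]]]:
    """Replacement weights per residue from the PAM250 substitution matrix.

    Log-odds scores are exponentiated (base 2) into weights; the identity
    substitution is excluded so every mutation changes the residue.
    """
    from Bio.Align import substitution_matrices

    pam = substitution_matrices.load("PAM250")
    standard = [a for a in pam.alphabet if a in "ACDEFGHIKLMNPQRSTVWY"]
    weights: dict[str, list[tuple[str, float]]] = {}
    for a in standard:
        weights[a] = [(b, 2.0 ** pam[a, b]) for b in standard if b != a]
    return weights


def mutate_loops(labeled: LabeledStructure, rate: float = 0.05,
                 substitution_table: dict[str, list[tuple[str, float]]] | None = None,
                 seed: int = 0) -> ProteinSequence:
    """Mutate loop/turn residues, leaving every strand untouched.

    floor(rate * N) loop-labeled positions are drawn without replacement;
    each replacement residue is drawn from the substitution-matrix row of
    the original (PAM250 by default), identity excluded.  If fewer loop
    positions exist than requested, all of them are mutated with a warning.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    table = substitution_table if substitution_table is not None \
        else _pam250_weights()
    rng = random.Random(seed)
    seq = labeled.sequence
    n_mut = int(rate * seq.n)
    loop_positions = [p for p in range(1, seq.n + 1)
                      if labeled.states[p - 1] == "L"
                      and seq.residue(p) in table]
    if n_mut > len(loop_positions):
        warnings.warn(f"only {len(loop_positions)} mutable loop positions for "
                      f"{n_mut} requested mutations", stacklevel=2)
        n_mut = len(loop_positions)
    chosen = sorted(rng.sample(loop_positions, n_mut))
    residues = list(seq.residues)
    for p in chosen:
        row = table[seq.residue(p)]
        letters = [b for b, _w in row]
        weights = [w for _b, w in row]
        residues[p - 1] = rng.choices(letters, weights=weights, k=1)[0]
    return ProteinSequence(id=f"{seq.id}|mut{rate:g}", residues="".join(residues))


def write_structure(structure: BarrelStructure, seq: ProteinSequence,
                    tsv_path: str | Path,
                    annotation_path: str | Path | None = None) -> None:
    """Write a solved structure as a TSV strand table (+ optional annotation).

    The TSV carries header lines with n, S, sigma and the total
    pseudo-energy, then one row per strand in sequence order: interval,
    barrel position, orientation and the relative shear toward the next
    barrel neighbour.  The annotation file uses the three-line paired
    format readable by :func:`barrelfold.seqio.read_annotation`.
    """
    labeled = structure_to_labeled(structure, seq)
    sigma_txt = ",".join(str(r) for r in structure.sigma.sigma)
    with open(tsv_path, "w") as fh:
        fh.write(f"#id\t{seq.id}\n#n\t{structure.n}\n#S\t{structure.S}\n")
        fh.write(f"#sigma\t{sigma_txt}\n#energy\t{structure.energy:.6f}\n")
        fh.write("strand\tstart\tend\tbarrel_position\tdirection\tfacing"
                 "\tshear_to_next\n")
        for i, strand in enumerate(structure.strands, start=1):
            p = structure.sigma.position(i)
            shear = (structure.relative_shears[p - 1] if structure.closed
                     else (structure.relative_shears[i - 1]
                           if i < structure.n else ""))
            fh.write(f"{i}\t{strand.nu}\t{strand.kappa}\t{p}"
                     f"\t{strand.direction}\t{strand.facing}\t{shear}\n")
    if annotation_path is not None:
        from .seqio import write_annotation
        write_annotation([labeled], annotation_path)
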