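"""The weighted strand-candidate DAG and its pseudo-energy attributes.

Vertices are candidate membrane-spanning strands (an interval of the
sequence plus a discretized orientation: up/down along the barrel axis and
odd-inward/odd-outward facing).  A directed edge (v, w) means the gap
between the two substrings can form a turn or loop; edges always point
forward along the sequence (kappa_v < nu_w - 2), so the graph is acyclic
and topological order coincides with the canonical lexicographic order on
(start, end, direction, facing).

Three pseudo-energy families decorate the graph:

* ``E_intr(v)`` — the strand on its own: how well its two faces match the
  lipid bilayer (hydrophobic out) and the channel (hydrophilic in), plus a
  strand-propensity term from the block filter.
* ``E_adj(v, w, s)`` — two strands laid side by side at relative shear s:
  a hydrogen-bond reward per aligned residue pair plus a side-chain pair
  term for pairs facing the same environment.  ``E_adj`` is defined for
  every ordered pair, not only edges, because barrel neighbours need not be
  sequence-consecutive.  Ordering is "barrel-forward": callers pass the
  pair in increasing barrel-position order.
* ``E_loop(v, w, t, s)`` — the connecting turn/loop when the two strands
  sit t positions apart on the barrel: a strong penalty when the loop is
  too short for the spanned distance or mostly hydrophobic, otherwise a
  weak hydropathy term.

The default model replaces atomistic side-chain terms with a pluggable
hydropathy-product potential; any object implementing the EnergyModel
protocol can stand in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Protocol, Sequence

from .config import RunConfig
from .filter import STRAND, BlockFrequencyTable, SegmentCandidate
from .seqio import ProteinSequence, hydropathy

__all__ = [
    "INFEASIBLE",
    "StrandCandidate",
    "EnergyModel",
    "HydropathyEnergyModel",
    "TableEnergyModel",
    "FoldGraph",
    "build_vertices",
    "build_edges",
    "build_graph",
]

#: sentinel for an unusable pairing; kept finite-checkable via math.isinf
INFEASIBLE = math.inf

Direction = Literal["up", "down"]

_DIR_ORDER = {"up": 0, "down": 1}
_FACE_ORDER = {"odd_inward": 0, "odd_outward": 1}


@dataclass(frozen=True)
class StrandCandidate:
    """A graph vertex: sequence interval plus discretized orientation."""

    nu: int
    kappa: int
    direction: Direction
    facing: str

    def __post_init__(self) -> None:
        if not 1 <= self.nu <= self.kappa:
            raise ValueError(f"bad interval ({self.nu},{self.kappa})")
        if self.direction not in _DIR_ORDER:
            raise ValueError(f"bad direction {self.direction!r}")
        if self.facing not in _FACE_ORDER:
            raise ValueError(f"bad facing {self.facing!r}")

    @property
    def length(self) -> int:
        return self.kappa - self.nu + 1

    def sort_key(self) -> tuple[int, int, int, int]:
        """Canonical lexicographic order on (start, end, orientation)."""
        return (self.nu, self.kappa, _DIR_ORDER[self.direction],
                _FACE_ORDER[self.facing])

    def lipid_facing(self, position: int) -> bool:
        """Does the residue at this absolute position face the bilayer?

        Odd positions face outward exactly when the strand is odd-outward.
        """
        return (position % 2 == 1) == (self.facing == "odd_outward")

    def axis_position(self, local: int) -> int:
        """Rung index along the barrel axis of local residue 0..length-1.

        Up strands run with the sequence; down strands against it, so the
        rung ladder is reversed.
        """
        return local if self.direction == "up" else self.length - 1 - local


class EnergyModel(Protocol):
    """Pluggable pseudo-energy callbacks over vertex indices."""

    def e_intr(self, i: int) -> float: ...

    def e_adj_s(self, i: int, j: int, s: int) -> float: ...

    def e_loop(self, i: int, j: int, t: int, s: int | None) -> float: ...

    def e_loop_top(self, i: int) -> float: ...

    def e_loop_bottom(self, i: int) -> float: ...


class HydropathyEnergyModel:
    """Default simplified potential computed from the sequence.

    Lower pseudo-energy is better throughout.
    """

    def __init__(self, seq: ProteinSequence,
                 vertices: Sequence[StrandCandidate],
                 table: BlockFrequencyTable | None = None,
                 config: RunConfig | None = None) -> None:
        self.seq = seq
        self.vertices = list(vertices)
        self.table = table
        self.config = config or RunConfig()

    def _h(self, position: int) -> float:
        return hydropathy(self.seq.residue(position))

    def e_intr(self, i: int) -> float:
        """Facing-aware hydropathy mismatch plus strand propensity.

        Each lipid-facing residue contributes -H(r) (rewarding hydrophobic)
        and each channel-facing residue +H(r) (rewarding hydrophilic); the
        unbiased block preference of the whole strand (rho = 1, no
        per-block offset) is subtracted with weight w_propensity so that
        genuinely strand-like substrings are cheaper and extensions into
        loop territory cost energy.
        """
        v = self.vertices[i]
        energy = 0.0
        for p in range(v.nu, v.kappa + 1):
            energy += -self._h(p) if v.lipid_facing(p) else self._h(p)
        if self.table is not None:
            segment = self.seq.segment(v.nu, v.kappa)
            if len(segment) >= self.table.l:
                energy -= self.config.w_propensity * self.table.segment_score(
                    segment, 1.0, STRAND)
        return energy

    def e_adj_s(self, i: int, j: int, s: int) -> float:
        """Pairing energy of two strands at relative shear s.

        Residues pair when their axis rungs differ by s (the second strand
        shifted s rungs).  Empty overlap is infeasible.  The definition is
        symmetric under (i, j, s) -> (j, i, -s).
        """
        v, w = self.vertices[i], self.vertices[j]
        cfg = self.config
        lo = max(0, s)
        hi = min(v.length - 1, w.length - 1 + s)
        if hi < lo:
            return INFEASIBLE
        energy = -cfg.hb_reward * (hi - lo + 1)
        for a in range(lo, hi + 1):
            qv, qw = a, a - s
            # invert axis_position to recover local residue indices
            pv = v.nu + (qv if v.direction == "up" else v.length - 1 - qv)
            pw = w.nu + (qw if w.direction == "up" else w.length - 1 - qw)
            if v.lipid_facing(pv) == w.lipid_facing(pw):
                energy -= cfg.pair_scale * self._h(pv) * self._h(pw)
        return energy

    def e_loop(self, i: int, j: int, t: int, s: int | None = None) -> float:
        """Turn/loop between sequence-consecutive strands at barrel distance t.

        Infeasible (strong penalty) when the gap cannot physically span t
        barrel positions or is mostly hydrophobic; otherwise the weak mean
        hydropathy of the gap.  The default potential does not use s.
        """
        v, w = self.vertices[i], self.vertices[j]
        if t < 1:
            raise ValueError("barrel distance t must be >= 1")
        gap = self.seq.segment(v.kappa + 1, w.nu - 1)
        cfg = self.config
        min_len = max(cfg.loop_len_bounds[0], cfg.loop_span_factor * t)
        hydrophobic = sum(1 for r in gap if hydropathy(r) > 0)
        if (len(gap) < min_len or len(gap) > cfg.loop_len_bounds[1]
                or 2 * hydrophobic > len(gap)):
            return cfg.loop_penalty
        return sum(hydropathy(r) for r in gap) / len(gap)

    def _terminal(self, start: int, end: int) -> float:
        if start > end:
            return 0.0
        gap = self.seq.segment(start, end)
        return sum(hydropathy(r) for r in gap) / len(gap)

    def e_loop_top(self, i: int) -> float:
        """Free N-terminal fragment before the first strand."""
        return self._terminal(1, self.vertices[i].nu - 1)

    def e_loop_bottom(self, i: int) -> float:
        """Free C-terminal fragment after the last strand."""
        return self._terminal(self.vertices[i].kappa + 1, self.seq.n)


class TableEnergyModel:
    """Energy model backed by explicit lookup tables (synthetic graphs)."""

    def __init__(self, intr: dict[int, float],
                 adj: dict[tuple[int, int], dict[int, float]],
                 loop: dict[tuple[int, int, int], float],
                 loop_top: dict[int, float],
                 loop_bottom: dict[int, float],
                 default_loop: float = 0.0) -> None:
        self.intr = intr
        self.adj = adj
        self.loop = loop
        self.loop_top = loop_top
        self.loop_bottom = loop_bottom
        self.default_loop = default_loop

    def e_intr(self, i: int) -> float:
        return self.intr[i]

    def e_adj_s(self, i: int, j: int, s: int) -> float:
        return self.adj.get((i, j), {}).get(s, INFEASIBLE)

    def e_loop(self, i: int, j: int, t: int, s: int | None = None) -> float:
        return self.loop.get((i, j, t), self.default_loop)

    def e_loop_top(self, i: int) -> float:
        return self.loop_top.get(i, 0.0)

    def e_loop_bottom(self, i: int) -> float:
        return self.loop_bottom.get(i, 0.0)


class FoldGraph:
    """The DAG over strand candidates with cached energy queries.

    ``vertices`` are in canonical order (which is also a topological
    order); dummy start/end vertices are implicit: ``start_ok`` marks
    vertices with an incoming edge from the start sentinel, ``end_ok``
    those with an outgoing edge to the end sentinel.
    """

    def __init__(self, vertices: Sequence[StrandCandidate],
                 successors: dict[int, list[int]],
                 start_ok: set[int], end_ok: set[int],
                 energy: EnergyModel,
                 config: RunConfig | None = None,
                 sequence_length: int | None = None) -> None:
        self.vertices = list(vertices)
        keys = [v.sort_key() for v in self.vertices]
        if keys != sorted(keys):
            raise ValueError("vertices must be in canonical order")
        self.successors = {i: sorted(successors.get(i, []))
                           for i in range(len(self.vertices))}
        for i, succ in self.successors.items():
            for j in succ:
                if self.vertices[i].kappa >= self.vertices[j].nu - 2:
                    raise ValueError(f"edge ({i},{j}) violates kappa < nu - 2")
        self.start_ok = set(start_ok)
        self.end_ok = set(end_ok)
        self.energy = energy
        self.config = config or RunConfig()
        self.sequence_length = sequence_length if sequence_length is not None \
            else (max((v.kappa for v in self.vertices), default=0))
        self._adj_cache: dict[tuple[int, int], tuple[float, int | None]] = {}

    # -- structure ----------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self.successors.values())

    def edges(self) -> list[tuple[int, int]]:
        return [(i, j) for i in sorted(self.successors)
                for j in self.successors[i]]

    # -- energies -----------------------------------------------------------

    def e_intr(self, i: int) -> float:
        return self.energy.e_intr(i)

    def e_adj_s(self, i: int, j: int, s: int) -> float:
        return self.energy.e_adj_s(i, j, s)

    def e_adj_opt(self, i: int, j: int) -> tuple[float, int | None]:
        """min_s E_adj(i, j, s) over the shear grid, with its argmin.

        Ties break toward the smallest shear; (inf, None) if no shear
        yields a usable pairing.
        """
        key = (i, j)
        if key not in self._adj_cache:
            best, best_s = INFEASIBLE, None
            for s in self.config.shear_grid():
                e = self.energy.e_adj_s(i, j, s)
                if e < best:
                    best, best_s = e, s
            self._adj_cache[key] = (best, best_s)
        return self._adj_cache[key]

    def e_loop(self, i: int, j: int, t: int, s: int | None = None) -> float:
        return self.energy.e_loop(i, j, t, s)

    def e_loop_top(self, i: int) -> float:
        return self.energy.e_loop_top(i)

    def e_loop_bottom(self, i: int) -> float:
        return self.energy.e_loop_bottom(i)

    # -- debugging ----------------------------------------------------------

    def dump_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("#vertex\tnu\tkappa\tdirection\tfacing\te_intr\n")
            for i, v in enumerate(self.vertices):
                fh.write(f"{i}\t{v.nu}\t{v.kappa}\t{v.direction}\t{v.facing}"
                         f"\t{self.e_intr(i):.4f}\n")
            fh.write("#edge\tfrom\tto\te_adj\ts_adj\n")
            for i, j in self.edges():
                e, s = self.e_adj_opt(i, j)
                fh.write(f"E\t{i}\t{j}\t{e:.4f}\t{s}\n")


def prune_candidates(seq: ProteinSequence,
                     candidates: Sequence[SegmentCandidate],
                     table: BlockFrequencyTable | None = None,
                     config: RunConfig | None = None) -> list[SegmentCandidate]:
    """Non-maximum suppression keeping the locally best strands by energy.

    Every sub-window and slight extension of a genuine strand also passes
    the filter, so the raw candidate list grows with the window-length
    range; the graph only stays linear in the sequence length when each
    region keeps a handful of variants.  Candidates are ranked by
    intrinsic-energy density (E_intr per residue, which penalizes both
    truncation — fewer scoring blocks per residue — and extension into
    loop territory) and greedily kept unless ``max_overlapping_candidates``
    already-kept segments overlap them by at least
    ``prune_overlap_fraction`` of the shorter segment.
    """
    config = config or RunConfig()
    probes = [StrandCandidate(c.start, c.end, "up", c.facing)
              for c in candidates]
    model = HydropathyEnergyModel(seq, probes, table, config)
    density = [model.e_intr(i) / probes[i].length for i in range(len(probes))]
    order = sorted(range(len(candidates)),
                   key=lambda i: (density[i], -candidates[i].length,
                                  candidates[i].start, candidates[i].facing))
    frac = config.prune_overlap_fraction
    max_over = config.max_overlapping_candidates
    kept: list[SegmentCandidate] = []
    for i in order:
        cand = candidates[i]
        overlapping = 0
        for other in kept:
            shorter = min(cand.length, other.length)
            overlap = min(cand.end, other.end) - max(cand.start, other.start) + 1
            if overlap >= frac * shorter:
                overlapping += 1
        if overlapping < max_over:
            kept.append(cand)
    kept.sort(key=lambda c: (c.start, c.end, c.facing))
    return kept


def build_vertices(seq: ProteinSequence,
                   candidates: Sequence[SegmentCandidate]) -> list[StrandCandidate]:
    """Expand filtered segments into oriented vertices, canonically sorted.

    Each candidate contributes one vertex per direction (its facing is
    already fixed by the filter; facing ties arrive as separate candidates).
    """
    vertices = {
        StrandCandidate(c.start, c.end, direction, c.facing)
        for c in candidates
        for direction in ("up", "down")
    }
    return sorted(vertices, key=StrandCandidate.sort_key)


def build_edges(vertices: Sequence[StrandCandidate],
                config: RunConfig | None = None,
                seq: ProteinSequence | None = None,
                table: BlockFrequencyTable | None = None,
                ) -> tuple[dict[int, list[int]], set[int], set[int]]:
    """Structural edges: (v, w) when the gap can be a turn or loop.

    Requires kappa_v < nu_w - 2, gap length within the loop bounds, and —
    when a sequence and trained table are supplied — a positive block
    statistic of the gap for the turn/loop conformation.  Start/end edges
    admit vertices whose leading/trailing fragment is short enough.
    """
    config = config or RunConfig()
    lo, hi = config.loop_len_bounds
    succ: dict[int, list[int]] = {i: [] for i in range(len(vertices))}
    for i, v in enumerate(vertices):
        for j, w in enumerate(vertices):
            if not v.kappa < w.nu - 2:
                continue
            gap_len = w.nu - v.kappa - 1
            if not lo <= gap_len <= hi:
                continue
            if seq is not None and table is not None and gap_len >= table.l:
                gap = seq.segment(v.kappa + 1, w.nu - 1)
                if table.segment_score(gap, config.rho, "other") <= 0:
                    continue
            succ[i].append(j)
    n_total = seq.n if seq is not None else max(v.kappa for v in vertices)
    start_ok = {i for i, v in enumerate(vertices)
                if v.nu - 1 <= config.max_leader}
    end_ok = {i for i, v in enumerate(vertices)
              if n_total - v.kappa <= config.max_trailer}
    return succ, start_ok, end_ok


def build_graph(seq: ProteinSequence, table: BlockFrequencyTable,
                config: RunConfig | None = None,
                prune: bool = True) -> FoldGraph:
    """Filter a sequence and assemble the full fold graph in one call.

    With ``prune`` (default), overlapping near-duplicate candidates are
    suppressed so the graph stays linear in the sequence length; pass
    ``prune=False`` to keep every filter-accepted segment.
    """
    from .filter import candidate_segments

    config = config or RunConfig()
    candidates = candidate_segments(seq, table, config)
    if prune:
        candidates = prune_candidates(seq, candidates, table, config)
    vertices = build_vertices(seq, candidates)
    succ, start_ok, end_ok = build_edges(vertices, config, seq, table)
    energy = HydropathyEnergyModel(seq, vertices, table, config)
    return FoldGraph(vertices, succ, start_ok, end_ok, energy, config,
                     sequence_length=seq.n)
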