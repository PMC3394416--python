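"""Constrained longest-path solvers for sheets, barrels and permuted barrels.

The folding problem is a longest-path problem on the strand-candidate DAG:
among all start-to-end paths with exactly n strand vertices whose relative
shears sum to the shear number S, find the one maximizing the criterion
C = -E, where

    E = sum E_intr(v)  +  sum E_loop over sequence-consecutive pairs
        +  sum E_adj over barrel-adjacent pairs.

Barrel adjacency is given by a circular permutation sigma with sigma(1)=1:
position p of the barrel holds the sigma(p)-th strand of the sequence.  For
the identity permutation barrel neighbours are sequence neighbours; Greek
key and Jelly roll motifs are non-trivial sigma.

Strands are laid down in *sequence* order (level k = number of strands
placed) but inserted at their permuted barrel position, so some energy
terms must wait: an adjacency term is payable once both its strands are
placed, and a loop term once the chain of placed adjacencies connecting
its two ends closes (the delta-A sets below).  The DP state at level k is
the tuple of "active" strand ranks — those a later term may still need —
together with the accumulated shear h; the optimum is read at k = n,
h = S.

Shear bookkeeping: every circular adjacency contributes its relative shear
exactly once, at the level where its later-in-sequence strand is placed
(the same rule that schedules E_adj).  The accumulated h at the end then
equals the sum around the closed barrel, which the constraint pins to S.

By default each adjacent pair is laid at its energy-optimal relative shear
s_adj(v, w); pass ``exhaustive_shear=True`` to branch over the whole shear
grid instead, which can reach (n, S) combinations the per-pair optimum
misses, at a grid-factor cost in states.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterator, Sequence

from .graph import FoldGraph, StrandCandidate

__all__ = [
    "BarrelPermutation",
    "BarrelStructure",
    "left_right",
    "conf_set",
    "adjacency_closure",
    "dp_active_set",
    "enumerate_circular_permutations",
    "greek_key_permutations",
    "fold_sheet",
    "fold_barrel",
    "fold_barrel_scan",
    "fold_barrel_permuted",
    "brute_force_fold",
    "evaluate_structure",
]


# ---------------------------------------------------------------------------
# permutation combinatorics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BarrelPermutation:
    """A circular strand arrangement: sigma(p) = sequence rank at position p.

    The reference position is fixed by sigma(1) = 1.
    """

    sigma: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.sigma)
        if n < 2:
            raise ValueError("a barrel needs at least 2 strands")
        if sorted(self.sigma) != list(range(1, n + 1)):
            raise ValueError(f"{self.sigma} is not a permutation of 1..{n}")
        if self.sigma[0] != 1:
            raise ValueError("reference position requires sigma(1) = 1")
        inverse = [0] * (n + 1)
        for p, rank in enumerate(self.sigma, start=1):
            inverse[rank] = p
        object.__setattr__(self, "_inverse", tuple(inverse))

    @classmethod
    def identity(cls, n: int) -> "BarrelPermutation":
        return cls(tuple(range(1, n + 1)))

    @property
    def n(self) -> int:
        return len(self.sigma)

    def rank(self, position: int) -> int:
        """sigma(position): the sequence rank placed at a barrel position."""
        return self.sigma[position - 1]

    def position(self, rank: int) -> int:
        """sigma^-1(rank): the barrel position of a sequence rank."""
        return self._inverse[rank]  # type: ignore[attr-defined]

    def is_identity(self) -> bool:
        return all(self.sigma[i] == i + 1 for i in range(self.n))

    def adjacent(self, i: int, j: int) -> bool:
        """Ranks i, j sit on neighbouring barrel positions (circularly)."""
        return abs(self.position(i) - self.position(j)) in (1, self.n - 1)


def left_right(sigma: BarrelPermutation, k: int) -> tuple[int, int]:
    """Ranks of the two barrel neighbours between which strand k is inserted.

    left_k = sigma(sigma^-1(k) - 1) (wrapping to sigma(n)),
    right_k = sigma(sigma^-1(k) + 1) (wrapping to 1).
    """
    n = sigma.n
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    p = sigma.position(k)
    left = sigma.rank(p - 1) if p > 1 else sigma.rank(n)
    right = sigma.rank(p + 1) if p < n else 1
    return left, right


def conf_set(sigma: BarrelPermutation, k: int) -> frozenset[int]:
    """The "active" strand ranks at construction level k.

    conf_k = {k} union {i < k : some not-yet-placed rank j > k is a barrel
    neighbour of i}.  These are the ranks whose vertex choice still matters
    to future insertions.
    """
    n = sigma.n
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    active = {k}
    for i in range(1, k):
        p = sigma.position(i)
        nb1 = sigma.rank(p - 1) if p > 1 else sigma.rank(n)
        nb2 = sigma.rank(p + 1) if p < n else sigma.rank(1)
        if nb1 > k or nb2 > k:
            active.add(i)
    return frozenset(active)


def _closure_levels(sigma: BarrelPermutation) -> list[frozenset[int]]:
    """A_k for k = 0..n: sequence-consecutive pairs linked by placed adjacencies.

    i in A_k means strands i and i+1 are connected through a chain of barrel
    adjacencies among the first k placed strands, so the loop between them
    is geometrically determined at level k.
    """
    n = sigma.n
    parent = list(range(n + 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    levels: list[frozenset[int]] = [frozenset()]
    placed: set[int] = set()
    for k in range(1, n + 1):
        placed.add(k)
        p = sigma.position(k)
        for q in (p - 1 if p > 1 else n, p + 1 if p < n else 1):
            j = sigma.rank(q)
            if j in placed:
                parent[find(j)] = find(k)
        levels.append(frozenset(
            i for i in range(1, n) if i + 1 <= k and find(i) == find(i + 1)))
    return levels


def adjacency_closure(sigma: BarrelPermutation, k: int
                      ) -> tuple[tuple[frozenset[int], ...], frozenset[int],
                                 frozenset[int]]:
    """(connected components, A_k, delta A_k) at level k.

    delta A_k lists the sequence-consecutive pairs (i, i+1) whose loop term
    becomes computable exactly when strand k is placed.
    """
    n = sigma.n
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    levels = _closure_levels(sigma)
    # rebuild components at level k for the support view
    comp: dict[int, set[int]] = {i: {i} for i in range(1, k + 1)}
    owner = {i: i for i in range(1, k + 1)}
    for i in range(1, k + 1):
        for j in range(1, k + 1):
            if i < j and sigma.adjacent(i, j) and owner[i] != owner[j]:
                a, b = owner[i], owner[j]
                comp[a] |= comp[b]
                for m in comp[b]:
                    owner[m] = a
                del comp[b]
    components = tuple(frozenset(c) for c in
                       sorted(comp.values(), key=min))
    return components, levels[k], levels[k] - levels[k - 1]


def dp_active_set(sigma: BarrelPermutation, k: int) -> tuple[int, ...]:
    """Sorted ranks the DP must keep in its level-k state tuple.

    This is conf_k extended with ranks whose sequence loop is still pending
    (i or i-1 not yet in A_k): those vertices are needed verbatim when the
    loop term finally resolves.  For identity and Greek-key permutations
    the extension adds nothing.
    """
    levels = _closure_levels(sigma)
    a_k = levels[k]
    active = set(conf_set(sigma, k))
    for i in range(1, k + 1):
        if (i < sigma.n and i not in a_k) or (i > 1 and i - 1 not in a_k):
            active.add(i)
    return tuple(sorted(active))


def enumerate_circular_permutations(n: int) -> Iterator[BarrelPermutation]:
    """All (n-1)! circular permutations with sigma(1) = 1, in lexicographic order."""
    if n < 2:
        raise ValueError("n must be >= 2")
    for rest in itertools.permutations(range(2, n + 1)):
        yield BarrelPermutation((1,) + rest)


def greek_key_permutations(n: int, include_identity: bool = False
                           ) -> Iterator[BarrelPermutation]:
    """Permutations differing from identity by disjoint Greek key motifs.

    A motif replaces four consecutive entries starting after a prefix of
    length i by (i+3, i+2, i+1, i+4) or (i+1, i+4, i+3, i+2).  Motifs are
    disjoint; arrangements breaking sigma(1) = 1 are skipped.
    """
    def build(start: int, entries: list[int], any_motif: bool
              ) -> Iterator[tuple[int, ...]]:
        if start > n:
            if any_motif or include_identity:
                yield tuple(entries)
            return
        # identity at this position
        yield from build(start + 1, entries + [start], any_motif)
        # a motif occupying positions start..start+3
        if start + 3 <= n:
            i = start - 1
            for motif in ((i + 3, i + 2, i + 1, i + 4),
                          (i + 1, i + 4, i + 3, i + 2)):
                candidate = entries + list(motif)
                if candidate[0] != 1:
                    continue
                yield from build(start + 4, candidate, True)

    for sig in build(1, [], False):
        yield BarrelPermutation(sig)


# ---------------------------------------------------------------------------
# result container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BarrelStructure:
    """A solved super-secondary structure.

    ``strands`` are in sequence order; ``relative_shears`` follow barrel
    positions for a closed barrel (entry p is the shear between positions p
    and p+1, the last entry closing the circle) and sequence order for an
    open sheet (n-1 entries).  ``criterion`` is C = -energy.
    """

    strands: tuple[StrandCandidate, ...]
    vertex_indices: tuple[int, ...]
    sigma: BarrelPermutation
    closed: bool
    relative_shears: tuple[int, ...]
    S: int
    energy: float
    dp_states_per_level: tuple[int, ...] = ()

    @property
    def n(self) -> int:
        return len(self.strands)

    @property
    def criterion(self) -> float:
        return -self.energy

    @property
    def per_strand_criterion(self) -> float:
        return self.criterion / self.n

    def __post_init__(self) -> None:
        expected = self.n if self.closed else self.n - 1
        if len(self.relative_shears) != expected:
            raise ValueError("wrong number of relative shears")
        if sum(self.relative_shears) != self.S:
            raise ValueError("relative shears do not sum to S")
        intervals = [(s.nu, s.kappa) for s in self.strands]
        if intervals != sorted(intervals) or any(
                a.kappa >= b.nu for a, b in zip(self.strands, self.strands[1:])):
            raise ValueError("strands must be sequence-ordered and disjoint")

    def strand_intervals(self) -> list[tuple[int, int]]:
        return [(s.nu, s.kappa) for s in self.strands]


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _other(direction: str) -> str:
    return "down" if direction == "up" else "up"

def _required_direction(g: str, position: int) -> str:
    """Antiparallel alternation: direction is set by barrel-position parity.

    g is the direction carried by odd positions (position 1 defines it).
    """
    return g if position % 2 == 1 else _other(g)


def _fits_remaining(graph: FoldGraph, vertex: int, remaining: int) -> bool:
    """Can `remaining` further strands still fit after this vertex?

    A lower bound using the minimal strand length and the minimal gap the
    edge rule admits; never discards a feasible path.
    """
    if remaining <= 0:
        return True
    need = remaining * (graph.config.strand_len_bounds[0] + 3)
    return graph.vertices[vertex].kappa + need <= graph.sequence_length


def _pair_candidates(graph: FoldGraph, i: int, j: int,
                     exhaustive: bool) -> list[tuple[float, int]]:
    """Usable (energy, shear) choices for laying strand j next to strand i."""
    if exhaustive:
        return [(e, s) for s in graph.config.shear_grid()
                if not math.isinf(e := graph.e_adj_s(i, j, s))]
    e, s = graph.e_adj_opt(i, j)
    return [] if s is None else [(e, s)]


def _arc_positions(sigma: BarrelPermutation, i: int) -> list[int]:
    """Pair indices of the forward barrel arc from rank i to rank i+1."""
    n = sigma.n
    p, target = sigma.position(i), sigma.position(i + 1)
    arc = []
    while p != target:
        arc.append(p)
        p = p % n + 1
    return arc


def _composed_shear(sigma: BarrelPermutation, pair_shears: dict[int, int],
                    i: int, S: int) -> int | None:
    """Composed relative shear between sequence-consecutive strands i, i+1.

    Summed along the forward arc of resolved adjacencies; if only the
    complementary arc is resolved, the closed-barrel constraint gives the
    value as S minus the complement.
    """
    arc = _arc_positions(sigma, i)
    if all(p in pair_shears for p in arc):
        return sum(pair_shears[p] for p in arc)
    complement = [p for p in range(1, sigma.n + 1) if p not in arc]
    if all(p in pair_shears for p in complement):
        return S - sum(pair_shears[p] for p in complement)
    return None


# ---------------------------------------------------------------------------
# open beta-sheet
# ---------------------------------------------------------------------------

def fold_sheet(graph: FoldGraph, n: int, S: int,
               exhaustive_shear: bool = False) -> BarrelStructure | None:
    """Optimal open n-strand sheet with total relative shear S.

    Returns None when no start-to-end path attains (n, S).
    """
    if n < 2:
        raise ValueError("a sheet needs at least 2 strands")
    prune = graph.config.shear_min >= 0
    # state: (last, h) -> (criterion, path, shears)
    states: dict[tuple[int, int], tuple[float, tuple[int, ...], tuple[int, ...]]] = {}
    for v in sorted(graph.start_ok):
        if not _fits_remaining(graph, v, n - 1):
            continue
        c = -graph.e_intr(v) - graph.e_loop_top(v)
        _keep(states, (v, 0), (c, (v,), ()))
    for level in range(2, n + 1):
        nxt: dict = {}
        for (u, h), (c, path, shears) in states.items():
            for w in graph.successors[u]:
                if graph.vertices[w].direction == graph.vertices[u].direction:
                    continue
                if not _fits_remaining(graph, w, n - level):
                    continue
                for e_adj, s in _pair_candidates(graph, u, w, exhaustive_shear):
                    h2 = h + s
                    if prune and h2 > S:
                        continue
                    c2 = (c - graph.e_intr(w) - e_adj
                          - graph.e_loop(u, w, 1, s))
                    _keep(nxt, (w, h2), (c2, path + (w,), shears + (s,)))
        states = nxt
    best = None
    for (u, h), (c, path, shears) in states.items():
        if h != S or u not in graph.end_ok:
            continue
        cand = (c - graph.e_loop_bottom(u), path, shears)
        if best is None or (cand[0], tuple(-x for x in cand[1])) > \
                (best[0], tuple(-x for x in best[1])):
            best = cand
    if best is None:
        return None
    c, path, shears = best
    return BarrelStructure(
        strands=tuple(graph.vertices[i] for i in path),
        vertex_indices=path, sigma=BarrelPermutation.identity(n),
        closed=False, relative_shears=shears, S=S, energy=-c)


def _keep(states: dict, key, value) -> None:
    """Keep the larger criterion; break ties toward the smaller vertex tuple."""
    old = states.get(key)
    if old is None or value[0] > old[0] or (
            value[0] == old[0] and value[1] < old[1]):
        states[key] = value


# ---------------------------------------------------------------------------
# closed barrel, identity permutation
# ---------------------------------------------------------------------------

def _barrel_final_states(graph: FoldGraph, n: int, s_cap: int,
                         exhaustive_shear: bool):
    """Run the identity-barrel DP; yield closed candidates (h, c, path, shears).

    The state tracks (first, last, h): the first vertex must be remembered
    for the closing adjacency between the last and first strands.
    """
    if n < 2:
        raise ValueError("a barrel needs at least 2 strands")
    prune = graph.config.shear_min >= 0
    states: dict[tuple[int, int, int],
                 tuple[float, tuple[int, ...], tuple[int, ...]]] = {}
    for v in sorted(graph.start_ok):
        if not _fits_remaining(graph, v, n - 1):
            continue
        c = -graph.e_intr(v) - graph.e_loop_top(v)
        _keep(states, (v, v, 0), (c, (v,), ()))
    for level in range(2, n + 1):
        nxt: dict = {}
        for (f, u, h), (c, path, shears) in states.items():
            for w in graph.successors[u]:
                if graph.vertices[w].direction == graph.vertices[u].direction:
                    continue
                if not _fits_remaining(graph, w, n - level):
                    continue
                for e_adj, s in _pair_candidates(graph, u, w, exhaustive_shear):
                    h2 = h + s
                    if prune and h2 > s_cap:
                        continue
                    c2 = (c - graph.e_intr(w) - e_adj
                          - graph.e_loop(u, w, 1, s))
                    _keep(nxt, (f, w, h2), (c2, path + (w,), shears + (s,)))
        states = nxt
    for (f, u, h), (c, path, shears) in states.items():
        if u not in graph.end_ok:
            continue
        if graph.vertices[u].direction == graph.vertices[f].direction:
            continue  # closing adjacency must also be antiparallel
        for e_adj, s in _pair_candidates(graph, u, f, exhaustive_shear):
            h2 = h + s
            if prune and h2 > s_cap:
                continue
            c2 = c - e_adj - graph.e_loop_bottom(u)
            yield h2, c2, path, shears + (s,)


def fold_barrel(graph: FoldGraph, n: int, S: int,
                exhaustive_shear: bool = False) -> BarrelStructure | None:
    """Optimal closed barrel with sequence-ordered strands (identity sigma)."""
    return fold_barrel_scan(graph, n, [S], exhaustive_shear)[S]


def fold_barrel_scan(graph: FoldGraph, n: int, S_values: Sequence[int],
                     exhaustive_shear: bool = False
                     ) -> dict[int, BarrelStructure | None]:
    """Solve the identity barrel for several shear numbers in one DP pass."""
    wanted = set(S_values)
    best: dict[int, tuple] = {}
    for h, c, path, shears in _barrel_final_states(
            graph, n, max(wanted), exhaustive_shear):
        if h not in wanted:
            continue
        cand = (c, path, shears)
        old = best.get(h)
        if old is None or cand[0] > old[0] or (
                cand[0] == old[0] and cand[1] < old[1]):
            best[h] = cand
    out: dict[int, BarrelStructure | None] = {}
    for S in S_values:
        if S not in best:
            out[S] = None
            continue
        c, path, shears = best[S]
        out[S] = BarrelStructure(
            strands=tuple(graph.vertices[i] for i in path),
            vertex_indices=path, sigma=BarrelPermutation.identity(n),
            closed=True, relative_shears=shears, S=S, energy=-c)
    return out


# ---------------------------------------------------------------------------
# closed barrel, general permutation
# ---------------------------------------------------------------------------

def fold_barrel_permuted(graph: FoldGraph, n: int, S: int,
                         sigma: BarrelPermutation,
                         exhaustive_shear: bool = False,
                         instrument: dict | None = None
                         ) -> BarrelStructure | None:
    """Optimal circle-attached path under an arbitrary circular permutation.

    Strands are added in sequence order and inserted at their permuted
    barrel position; adjacency terms are paid when their second strand
    arrives, loop terms when the interleaving adjacencies resolve their
    composed shear.  ``instrument``, if given, receives
    ``states_per_level``: the number of distinct active tuples per level.
    """
    if sigma.n != n:
        raise ValueError(f"permutation size {sigma.n} != n={n}")
    if n < 2:
        raise ValueError("a barrel needs at least 2 strands")
    prune = graph.config.shear_min >= 0
    levels_A = _closure_levels(sigma)
    active_sets = {k: dp_active_set(sigma, k) for k in range(1, n + 1)}
    pos = {k: sigma.position(k) for k in range(1, n + 1)}
    states_per_level: list[int] = []

    # state key: (g, z, h); value: (criterion, path, pair_shears-as-tuple)
    states: dict[tuple, tuple[float, tuple[int, ...], tuple]] = {}
    for v in sorted(graph.start_ok):
        if not _fits_remaining(graph, v, n - 1):
            continue
        g = graph.vertices[v].direction  # position 1 is odd: defines parity
        c = -graph.e_intr(v) - graph.e_loop_top(v)
        _keep(states, (g, (v,), 0), (c, (v,), ()))
    states_per_level.append(len({key[1] for key in states}))

    for k in range(2, n + 1):
        left_k, right_k = left_right(sigma, k)
        delta = levels_A[k] - levels_A[k - 1]
        prev_active = active_sets[k - 1]
        cur_active = active_sets[k]
        idx_prev = {rank: i for i, rank in enumerate(prev_active)}
        nxt: dict = {}
        for (g, z, h), (c, path, pairs) in states.items():
            y = {rank: z[i] for rank, i in idx_prev.items()}
            last = y[k - 1]
            need_dir = _required_direction(g, pos[k])
            for w in graph.successors[last]:
                if graph.vertices[w].direction != need_dir:
                    continue
                if not _fits_remaining(graph, w, n - k):
                    continue
                # adjacency pairs resolved by placing strand k
                resolved: list[tuple[int, int, int]] = []  # (pair index, i, j)
                if left_k < k:
                    pl = pos[k] - 1 if pos[k] > 1 else n
                    resolved.append((pl, y[left_k], w))
                if right_k < k:
                    resolved.append((pos[k], w, y[right_k]))
                choice_lists = [_pair_candidates(graph, i, j, exhaustive_shear)
                                for (_p, i, j) in resolved]
                if any(not ch for ch in choice_lists):
                    continue
                avail = dict(y)
                avail[k] = w
                for combo in itertools.product(*choice_lists):
                    h2 = h + sum(s for _e, s in combo)
                    if prune and h2 > S:
                        continue
                    pair_shears = dict(pairs)
                    for (p, _i, _j), (_e, s) in zip(resolved, combo):
                        pair_shears[p] = s
                    c2 = c - graph.e_intr(w) - sum(e for e, _s in combo)
                    for i in delta:
                        t = (pos[i + 1] - pos[i]) % n
                        s_star = _composed_shear(sigma, pair_shears, i, S)
                        c2 -= graph.e_loop(avail[i], avail[i + 1], t, s_star)
                    if k == n:
                        if w not in graph.end_ok:
                            continue
                        c2 -= graph.e_loop_bottom(w)
                    z2 = tuple(avail[r] for r in cur_active)
                    _keep(nxt, (g, z2, h2),
                          (c2, path + (w,), tuple(sorted(pair_shears.items()))))
        states = nxt
        states_per_level.append(len({key[1] for key in states}))

    if instrument is not None:
        instrument["states_per_level"] = states_per_level
    best = None
    for (g, z, h), (c, path, pairs) in states.items():
        if h != S:
            continue
        if best is None or c > best[0] or (c == best[0] and path < best[1]):
            best = (c, path, pairs)
    if best is None:
        return None
    c, path, pairs = best
    shear_by_pair = dict(pairs)
    return BarrelStructure(
        strands=tuple(graph.vertices[i] for i in path),
        vertex_indices=path, sigma=sigma, closed=True,
        relative_shears=tuple(shear_by_pair[p] for p in range(1, n + 1)),
        S=S, energy=-c,
        dp_states_per_level=tuple(states_per_level))


# ---------------------------------------------------------------------------
# exhaustive oracle and objective evaluation
# ---------------------------------------------------------------------------

def evaluate_structure(graph: FoldGraph, vertex_indices: Sequence[int],
                       sigma: BarrelPermutation, closed: bool,
                       pair_shears: Sequence[int]) -> float:
    """Total pseudo-energy of an explicit structure (the objective).

    ``pair_shears`` follow barrel positions for a closed barrel (n values,
    entry p for the adjacency between positions p and p+1) and sequence
    order for a sheet (n-1 values).  This is the definitional objective the
    dynamic programs must agree with.
    """
    n = len(vertex_indices)
    v = list(vertex_indices)
    energy = sum(graph.e_intr(i) for i in v)
    energy += graph.e_loop_top(v[0]) + graph.e_loop_bottom(v[-1])
    if closed:
        shear = {p: pair_shears[p - 1] for p in range(1, n + 1)}
        for p in range(1, n + 1):
            a = sigma.rank(p)
            b = sigma.rank(p % n + 1)
            energy += graph.e_adj_s(v[a - 1], v[b - 1], shear[p])
        for i in range(1, n):
            t = (sigma.position(i + 1) - sigma.position(i)) % n
            s_star = sum(shear[p] for p in _arc_positions(sigma, i))
            energy += graph.e_loop(v[i - 1], v[i], t, s_star)
    else:
        for i in range(1, n):
            s = pair_shears[i - 1]
            energy += graph.e_adj_s(v[i - 1], v[i], s)
            energy += graph.e_loop(v[i - 1], v[i], 1, s)
    return energy


def _paths(graph: FoldGraph, n: int) -> Iterator[tuple[int, ...]]:
    """All start-to-end paths of exactly n strand vertices."""
    def extend(path: tuple[int, ...]) -> Iterator[tuple[int, ...]]:
        if len(path) == n:
            if path[-1] in graph.end_ok:
                yield path
            return
        for w in graph.successors[path[-1]]:
            yield from extend(path + (w,))

    for v in sorted(graph.start_ok):
        yield from extend((v,))


def brute_force_fold(graph: FoldGraph, n: int, S: int,
                     sigma: BarrelPermutation | None = None,
                     closed: bool = True,
                     exhaustive_shear: bool = False,
                     guard: int = 16) -> BarrelStructure | None:
    """Exhaustive-enumeration oracle for the folding problem.

    Enumerates every admissible vertex tuple (and, in exhaustive-shear
    mode, every shear assignment) and evaluates the full objective.  Only
    usable on small graphs; ``guard`` bounds the vertex count.
    """
    if graph.n_vertices > guard:
        raise ValueError(f"brute force guarded at {guard} vertices")
    sigma = sigma or BarrelPermutation.identity(n)
    if sigma.n != n:
        raise ValueError("permutation size mismatch")
    grid = list(graph.config.shear_grid())
    best: tuple | None = None

    def consider(c: float, path: tuple[int, ...], shears: tuple[int, ...]):
        nonlocal best
        if best is None or c > best[0] or (c == best[0] and path < best[1]):
            best = (c, path, shears)

    for path in _paths(graph, n):
        # antiparallel alternation by barrel-position parity
        dirs = [graph.vertices[i].direction for i in path]
        ok = all(
            (dirs[k - 1] == dirs[0]) == (sigma.position(k) % 2 == 1)
            for k in range(1, n + 1)) if closed else all(
            dirs[k] != dirs[k - 1] for k in range(1, n))
        if not ok:
            continue
        if closed:
            pairs = [(sigma.rank(p), sigma.rank(p % n + 1))
                     for p in range(1, n + 1)]
        else:
            pairs = [(i, i + 1) for i in range(1, n)]
        endpoints = [(path[a - 1], path[b - 1]) for a, b in pairs]
        if exhaustive_shear:
            shear_options = [
                [s for s in grid
                 if not math.isinf(graph.e_adj_s(i, j, s))]
                for i, j in endpoints]
            if any(not opts for opts in shear_options):
                continue
            for assignment in itertools.product(*shear_options):
                if sum(assignment) != S:
                    continue
                e = evaluate_structure(graph, path, sigma, closed, assignment)
                consider(-e, path, tuple(assignment))
        else:
            opts = [graph.e_adj_opt(i, j) for i, j in endpoints]
            if any(s is None for _e, s in opts):
                continue
            assignment = tuple(s for _e, s in opts)
            if sum(assignment) != S:
                continue
            e = evaluate_structure(graph, path, sigma, closed, assignment)
            consider(-e, path, assignment)

    if best is None:
        return None
    c, path, shears = best
    return BarrelStructure(
        strands=tuple(graph.vertices[i] for i in path),
        vertex_indices=path, sigma=sigma, closed=closed,
        relative_shears=shears, S=S, energy=-c)
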