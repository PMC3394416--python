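# Methods

## The model

Transmembrane β-barrel (TMB) proteins of the outer membrane close a ring of
n antiparallel β-strands around a central channel.  In a regular barrel the
backbone geometry is fixed by two integers: the strand count n and the
shear number S — the ordinal offset, along the hydrogen-bond ladder,
between a residue and its image after one full turn around the barrel.  S
decomposes into per-adjacent-pair *relative shears* s_i whose sum around
the closed barrel equals S, and it sets the strand tilt against the barrel
axis through

    tan θ = h·S / (d·n)

with h the rise per residue (3.3 Å) and d the inter-strand distance
(4.4 Å).  Known barrels have even n in 8..22, even S in [n, 2n], positive
shear (right-handed tilt), and observed tilts cluster around 41–49°.

`barrelfold` treats structure prediction as a constrained longest-path
problem.  Candidate membrane-spanning strands become vertices of a DAG;
an edge (v, w) means the gap between the two substrings can form a turn or
loop (gap ≥ 2 residues, i.e. κ_v < ν_w − 2, length within loop bounds,
turn-like composition).  Each vertex carries a discretized orientation:
up/down along the axis and odd-inward/odd-outward facing (which residue
parity lines the channel).  A structure is a start-to-end path of exactly
n vertices arranged on a circle by a permutation σ with σ(1) = 1 — the
identity for ordinary barrels, non-trivial for Greek key / Jelly roll
topologies — minimizing the pseudo-energy

    E = Σ_v E_intr(v) + Σ_(v,w)∈P E_loop(v,w) + Σ_(v,w)∈σ(P) E_adj(v,w)

subject to Σ s_adj over the n circular adjacencies = S.  The solvers
maximize the criterion C = −E.

## Strand filter

Two necessary conditions select candidate segments:

* **Amphipathicity.**  The mean Kyte–Doolittle hydropathies of the two
  faces (absolute even / odd positions) must satisfy max(Hᵉ, Hᵒ) > ζ⁻ and
  min(Hᵉ, Hᵒ) < ζ⁺ with ζ⁻ = −1, ζ⁺ = +1: one hydrophobic face for the
  bilayer, one hydrophilic for the channel.  The more hydrophobic parity
  fixes the facing; an exact tie emits both orientations.
* **Block information.**  From a labeled training set we count l-residue
  blocks (l = 3) lying fully inside one conformation run and score a
  segment by Ĩ = Σ_blocks log[(f_strand,r/f_strand,·)/(f_other,r/f_other,·)]
  − (#blocks)·log ρ, accepting when Ĩ > 0.  ρ defaults to 2/3, a permissive
  per-block bonus suited to small training sets.  Natural logarithms are
  used; only the sign of Ĩ matters for acceptance.

Smoothing adds a pseudocount to every cell of the 20^l block space,
applied lazily so the marginal identities hold exactly.  The default
pseudocount is 0.1, not add-one: the block space (8000 cells at l = 3)
dwarfs any realistic training mass, and add-one smoothing flattens the
log-odds until boundary-straddling windows score like genuine strands.

Every sub-window and slight extension of a true strand also passes both
tests, so graph construction prunes near-duplicates by non-maximum
suppression ranked on intrinsic-energy density (E_intr per residue),
keeping at most `max_overlapping_candidates` (default 2) variants per
region.  This enforces the linear-size premise |V| ≤ k·N the complexity
results rely on; `build_graph(..., prune=False)` keeps everything.

## Pseudo-energies

The original side-chain terms of this family of methods come from rotamer
libraries and force-field partial charges; `barrelfold` ships a pluggable
`EnergyModel` protocol with a simplified hydropathy-based default (any
object implementing the protocol can replace it):

* `E_intr(v)` = Σ_lipid-facing −H(r) + Σ_channel-facing +H(r)
  − w_prop·Ĩ(strand; v) with w_prop = 2 and Ĩ evaluated at ρ = 1 (no
  per-block bonus inside an energy).  Hydrophobic residues are rewarded on
  the bilayer face, hydrophilic on the channel face, and the propensity
  term makes every extension of a strand into loop territory cost energy.
* `E_adj(v, w, s)` aligns the two strands rung-by-rung under relative
  shear s (directions orient the rung ladders; empty overlap is an
  infeasible +∞).  Energy = −hb_reward per aligned pair (0.5, the
  hydrogen-bond term) − pair_scale·H(a)·H(b) (0.2) for aligned pairs
  facing the same environment.  It satisfies E_adj(v,w,s) = E_adj(w,v,−s);
  callers pass pairs in barrel-forward order.  `e_adj_opt` scans the shear
  grid (default 0..4, non-negative because known barrels tilt one way) and
  defines s_adj as the argmin, smallest shear on ties.
* `E_loop(v, w, t, s)` for a loop spanning t barrel positions: a strong
  penalty (1000) when the gap is shorter than max(loop_min, 2t) residues,
  longer than loop_max, or majority-hydrophobic; otherwise the weak mean
  hydropathy of the gap.  The default is s-independent (see limitations).
  Free N-/C-terminal fragments contribute their mean hydropathy.

Weights were set from the planted-fixture analysis (hydrogen-bond reward
small enough that one extra aligned loop-residue pair never outweighs the
propensity penalty of extending a strand) and are all configurable.

## Dynamic programming

Three solvers share the objective and an exhaustive-enumeration oracle
(`brute_force_fold`, guarded at 16 vertices) that defines it:

* **Open sheet** (identity order, no closure): states (last vertex,
  accumulated shear h); O(|V|+|E|) per shear slice.
* **Identity barrel**: states (first, last, h) — the first vertex must be
  remembered for the closing adjacency; a final step adds E_adj(last,
  first) and the closing shear.  `fold_barrel_scan` reads every S of an
  (n, S) sweep out of one DP pass.
* **Permuted barrel**: strands are added in sequence order k = 1..n and
  inserted at barrel position σ⁻¹(k).  The state is the tuple of *active*
  ranks — conf_k = {k} ∪ {i < k with a not-yet-placed barrel neighbour} —
  plus h.  An adjacency term is paid when its later-in-sequence strand is
  placed; a loop term when the chain of placed adjacencies linking its two
  ends closes (the δA_k sets, computed by union–find).  State counts per
  level are bounded by |V|^max_k|conf_k| (instrumented and asserted in
  tests); for permutations made of disjoint Greek key motifs
  max|conf_k| ≤ 4.

Shear bookkeeping departs from the insertion-correction formulation in
one equivalent way: each circular adjacency contributes its s_adj exactly
once, at the level where its later strand is placed, so the accumulated h
telescopes directly to Σ_(v,w)∈σ(P) s_adj and the optimum is read at
(k = n, h = S).  This avoids composed-shear corrections for pairs whose
interior strands have been forgotten.

Two further placement rules: consecutive barrel positions must hold
antiparallel strands (direction is fixed by barrel-position parity up to
one global flip, carried as a state bit), and a cheap reachability bound
prunes states that cannot fit the remaining strands.

**Fixed vs exhaustive shear.**  By default each pair sits at its optimal
s_adj, which makes Σ s_adj a property of the chosen vertices — faithful to
the recurrences, but most (n, S) couples then have no solution.
`exhaustive_shear=True` branches over the whole shear grid per adjacency
(grid-factor more states); `classify` uses it because scanning S is
meaningless otherwise.

The DP-internal active set extends conf_k with ranks whose sequence loop
is still pending, because the conf_k formula can in principle retire a
rank before a long-arc loop resolves; for identity and Greek-key
permutations the extension adds nothing.

## Classification

`classify` enumerates the admissible (n, S) couples for the sequence
length, solves the closed barrel for each, and accepts the sequence as TMB
when a structure exists and its per-strand criterion C/n reaches
`classify_threshold`.  The 0.85 default is nominal: the threshold's scale
is tied to the energy parameterization, and the simplified default
potential yields much larger criteria on synthetic barrels, so the
threshold matters mainly as a knob when users calibrate their own
potential.  Sequences with too few candidates are rejected outright.

`permutation_landscape` evaluates a supplied family of permutations
(e.g. all (n−1)! circular ones) at fixed (n, S) and reports the feasible
set within a relative energy window (default 2%) of the minimum.

Metrics follow the conventions of the TMB-prediction literature:
"specificity" is precision TP/(TP+FP), "sensitivity" recall, F combines
exactly those two, Q2 is percent correct, and MCC is 0 whenever a
confusion-matrix marginal vanishes.  Strand-level matching pairs a
predicted strand with at most one ground-truth strand overlapping ≥ 50%
of the shorter.

`mutate_loops` supports robustness experiments: it substitutes a fraction
(⌊rate·N⌋, default 5%) of loop-labeled residues, drawing replacements from
the PAM250 row of the original (scores exponentiated base 2 into weights,
identity excluded), never touching strands.

## Synthetic data

`fixtures` plants ground truth without external data.  A barrel fixture is
n_strands (default 8) strands of strand_len (10) residues strictly
alternating hydrophobic (I/L/V/F) and hydrophilic (D/E/N/Q) letters,
joined by loop_len (4) flexible residues (G/S/P) with 5-residue termini;
its planted geometry is uniform relative shear 1, S = n.  Training sets
vary n, strand and loop lengths per item.  Default tests train on 40
fixtures — the scale of the curated non-redundant sets used for this
problem — and a 10-fixture set exercises the small-training regime.

What the fixtures do **not** emulate: sequence homology and composition
bias of real proteomes, long extracellular loops, broken or shared
strands, signal peptides, and any real pairwise contact statistics.
Passing the planted-recovery tests therefore shows internal consistency
of filter + graph + solver, not predictive accuracy on real proteins,
which would require the atomistic pairwise terms this package deliberately
replaces.  Random fold graphs (≤ 16 vertices, table-backed energies) are
the substrate for the DP-versus-oracle equivalence suite.

## Numerical and design choices

* Coordinates are 1-based inclusive everywhere; I/O converts at the edge.
* Non-standard residues are accepted with neutral hydropathy 0.0 and a
  warning; `strict=True` raises.
* Ties among equal-criterion solutions resolve to the lexicographically
  smallest vertex tuple — solvers are deterministic functions of
  (graph, n, S, σ).
* Infeasible (n, S, σ) returns `None`, never an exception.
* Loop geometric feasibility uses min length 2·t residues for a loop
  skipping to barrel distance t (configurable factor); the loop-length
  bounds default to (2, 18): 2 is the smallest gap the edge rule admits,
  18 spans typical turn regions without letting whole-strand skips
  dominate.
* Composed relative shears s*_adj for distance-t loops are summed along
  the forward barrel arc when its strands are still active, or obtained as
  S minus the complementary arc; the structure report always carries exact
  per-pair shears recomputed from the traceback.
* Objective recomputation from any returned structure agrees with the
  DP criterion to 1e−9 (asserted in tests).

## Known limitations

* The default potential is a screening-grade surrogate: no electrostatics,
  rotamers, depth-dependent dielectric, and no asymmetry between the
  extracellular and periplasmic environments; replacing it means
  implementing the small `EnergyModel` protocol.
* User-supplied loop potentials that depend on the composed shear s are
  evaluated with s = None inside the permuted DP whenever the resolving
  arc's interior vertices are no longer active; the oracle always passes
  the exact composed value.  The default potential ignores s, so the
  shipped solvers and oracle agree exactly.
* α-helical membrane proteins, multi-domain barrels and broken strands are
  out of scope; tree-decomposition speedups of the permuted DP are not
  implemented.
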