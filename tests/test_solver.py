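import pytest

from barrelfold import (BarrelPermutation, RunConfig, adjacency_closure,
                        brute_force_fold, conf_set, dp_active_set,
                        enumerate_circular_permutations, evaluate_structure,
                        fold_barrel, fold_barrel_permuted, fold_barrel_scan,
                        fold_sheet, greek_key_permutations, left_right,
                        make_random_graph)
from barrelfold.graph import FoldGraph, StrandCandidate, TableEnergyModel
from barrelfold.solver import _arc_positions, _composed_shear

SIGMA_5436 = BarrelPermutation((1, 2, 5, 4, 3, 6))
SIGMA_3654 = BarrelPermutation((1, 2, 3, 6, 5, 4))


class TestPermutationCombinatorics:
    def test_left_right_worked_example(self):
        expected = {1: (6, 2), 2: (1, 5), 3: (4, 6),
                    4: (5, 3), 5: (2, 4), 6: (3, 1)}
        for k, pair in expected.items():
            assert left_right(SIGMA_5436, k) == pair

    def test_left_right_identity(self):
        sigma = BarrelPermutation.identity(8)
        assert left_right(sigma, 1) == (8, 2)
        assert left_right(sigma, 8) == (7, 1)
        for k in range(2, 8):
            assert left_right(sigma, k) == (k - 1, k + 1)

    def test_conf_worked_example(self):
        expected = [{1}, {1, 2}, {1, 2, 3}, {1, 2, 3, 4}, {1, 3, 5}, {6}]
        for k, want in enumerate(expected, start=1):
            assert conf_set(SIGMA_5436, k) == frozenset(want)

    def test_conf_identity_keeps_closure_reference(self):
        sigma = BarrelPermutation.identity(8)
        for k in range(2, 8):
            assert conf_set(sigma, k) == frozenset({1, k})
        assert conf_set(sigma, 8) == frozenset({8})

    def test_adjacency_closure_worked_example(self):
        _comp, a4, _d4 = adjacency_closure(SIGMA_5436, 4)
        assert a4 == frozenset({1, 3})
        _comp, a5, d5 = adjacency_closure(SIGMA_5436, 5)
        assert a5 == frozenset({1, 2, 3, 4})
        assert d5 == frozenset({2, 4})  # loops (2,3) and (4,5) resolve here

    def test_adjacency_closure_identity(self):
        sigma = BarrelPermutation.identity(6)
        for k in range(2, 7):
            _c, _a, delta = adjacency_closure(sigma, k)
            assert delta == frozenset({k - 1})

    def test_dp_active_extends_conf(self):
        for sigma in (SIGMA_5436, SIGMA_3654, BarrelPermutation.identity(6)):
            for k in range(1, 7):
                assert set(conf_set(sigma, k)) <= set(dp_active_set(sigma, k))

    def test_composed_shear_worked_example(self):
        # s*(2,3) composes along barrel positions 2,3,4: pairs
        # (2,5), (5,4), (4,3) in sequence-rank terms
        assert _arc_positions(SIGMA_5436, 2) == [2, 3, 4]
        pair_shears = {1: 9, 2: 1, 3: 2, 4: 3, 5: 9, 6: 9}
        assert _composed_shear(SIGMA_5436, pair_shears, 2, S=0) == 6

    def test_composed_shear_from_complement(self):
        # only the complementary arc resolved: closed-barrel sum gives it
        pair_shears = {1: 1, 5: 1, 6: 2}
        assert _composed_shear(SIGMA_5436, pair_shears, 2, S=10) == 6

    def test_invalid_permutations_rejected(self):
        with pytest.raises(ValueError):
            BarrelPermutation((2, 1, 3))
        with pytest.raises(ValueError):
            BarrelPermutation((1, 2, 2))
        with pytest.raises(ValueError):
            left_right(SIGMA_5436, 7)


class TestPermutationEnumeration:
    @pytest.mark.parametrize("n,count", [(2, 1), (3, 2), (4, 6), (8, 5040)])
    def test_counts(self, n, count):
        perms = list(enumerate_circular_permutations(n))
        assert len(perms) == count
        assert len({p.sigma for p in perms}) == count

    def test_greek_key_contains_printed_examples(self):
        sigmas = {p.sigma for p in greek_key_permutations(6)}
        assert SIGMA_5436.sigma in sigmas
        assert SIGMA_3654.sigma in sigmas

    def test_greek_key_all_reference_fixed(self):
        for n in (8, 10):
            for p in greek_key_permutations(n):
                assert p.sigma[0] == 1


def chain_graph(energies=None, s_values=None, n=4):
    """A deterministic single-chain graph of n vertices."""
    vertices = [StrandCandidate(1 + 12 * i, 8 + 12 * i,
                                "up" if i % 2 == 0 else "down", "odd_inward")
                for i in range(n)]
    succ = {i: ([i + 1] if i + 1 < n else []) for i in range(n)}
    grid = range(0, 5)
    e = energies or {i: -1.0 for i in range(n)}
    s_opt = s_values or {}
    adj = {}
    for i in range(n):
        for j in range(n):
            if i != j:
                target = s_opt.get((i, j), 1)
                adj[(i, j)] = {s: -5.0 + abs(s - target) for s in grid}
    model = TableEnergyModel(e, adj, {}, {}, {})
    return FoldGraph(vertices, succ, set(range(n)), set(range(n)), model,
                     RunConfig())


class TestSheetAndBarrel:
    def test_unique_chain_returned(self):
        g = chain_graph()
        st = fold_sheet(g, 4, 3)  # optimal shears are all 1: sum = 3
        assert st is not None
        assert st.vertex_indices == (0, 1, 2, 3)
        assert st.relative_shears == (1, 1, 1)
        assert sum(st.relative_shears) == st.S == 3

    def test_infeasible_is_none_not_exception(self):
        g = chain_graph()
        assert fold_sheet(g, 4, 100) is None
        assert fold_barrel(g, 4, 100) is None
        assert fold_barrel_permuted(g, 4, 100,
                                    BarrelPermutation.identity(4)) is None

    def test_exhaustive_mode_reaches_other_shear_sums(self):
        g = chain_graph()
        assert fold_sheet(g, 4, 5) is None  # fixed per-pair optima sum to 3
        st = fold_sheet(g, 4, 5, exhaustive_shear=True)
        assert st is not None and sum(st.relative_shears) == 5

    def test_objective_shift_by_intrinsic_constant(self):
        g1 = chain_graph()
        g2 = chain_graph(energies={i: -1.0 + 2.5 for i in range(4)})
        a, b = fold_sheet(g1, 4, 3), fold_sheet(g2, 4, 3)
        assert b.criterion == pytest.approx(a.criterion - 4 * 2.5)
        assert a.vertex_indices == b.vertex_indices

    def test_barrel_scan_matches_single_solves(self):
        g = make_random_graph(10, seed=11)
        scan = fold_barrel_scan(g, 4, [2, 4, 6, 8])
        for S in (2, 4, 6, 8):
            single = fold_barrel(g, 4, S)
            if single is None:
                assert scan[S] is None
            else:
                assert scan[S].criterion == pytest.approx(single.criterion)

    def test_closing_term_contributes(self):
        g = make_random_graph(10, seed=2)
        barrel = fold_barrel(g, 4, 4)
        sheet = fold_sheet(g, 4, 4)
        if barrel is not None and sheet is not None:
            # the closed objective carries one more (negative) E_adj term
            closure = barrel.relative_shears[-1]
            assert barrel.criterion != pytest.approx(sheet.criterion)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("exhaustive", [False, True])
    def test_identity_barrel_and_sheet(self, seed, exhaustive):
        g = make_random_graph(10, seed=seed)
        for S in (3, 4, 6):
            for closed in (True, False):
                if closed:
                    dp = fold_barrel(g, 4, S, exhaustive_shear=exhaustive)
                else:
                    dp = fold_sheet(g, 4, S, exhaustive_shear=exhaustive)
                oracle = brute_force_fold(g, 4, S, closed=closed,
                                          exhaustive_shear=exhaustive)
                assert (dp is None) == (oracle is None)
                if dp is not None:
                    assert dp.criterion == pytest.approx(oracle.criterion)
                    assert dp.vertex_indices == oracle.vertex_indices
                    assert sum(dp.relative_shears) == S

    @pytest.mark.parametrize("sigma", [SIGMA_5436, SIGMA_3654])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_greek_key_permuted(self, sigma, seed):
        g = make_random_graph(12, seed=seed)
        for S in (4, 6):
            dp = fold_barrel_permuted(g, 6, S, sigma)
            oracle = brute_force_fold(g, 6, S, sigma=sigma)
            assert (dp is None) == (oracle is None)
            if dp is not None:
                assert dp.criterion == pytest.approx(oracle.criterion)
                assert dp.vertex_indices == oracle.vertex_indices

    def test_identity_permuted_matches_direct_barrel(self):
        for seed in range(5):
            g = make_random_graph(10, seed=seed)
            a = fold_barrel(g, 4, 4)
            b = fold_barrel_permuted(g, 4, 4, BarrelPermutation.identity(4))
            assert (a is None) == (b is None)
            if a is not None:
                assert a.criterion == pytest.approx(b.criterion)
                assert a.vertex_indices == b.vertex_indices

    def test_objective_recomputation_matches_dp(self):
        for seed in range(5):
            g = make_random_graph(12, seed=seed)
            st = fold_barrel_permuted(g, 6, 6, SIGMA_5436)
            if st is None:
                continue
            e = evaluate_structure(g, st.vertex_indices, st.sigma, True,
                                   st.relative_shears)
            assert e == pytest.approx(st.energy, abs=1e-9)

    def test_oracle_guard(self):
        with pytest.raises(ValueError):
            brute_force_fold(make_random_graph(16, seed=0), 4, 4, guard=12)

    def test_determinism(self):
        g = make_random_graph(10, seed=7)
        a = fold_barrel(g, 4, 4)
        b = fold_barrel(g, 4, 4)
        if a is not None:
            assert a == b


class TestStateInstrumentation:
    def test_states_bounded_by_conf_power(self):
        for seed in (0, 1):
            g = make_random_graph(12, seed=seed)
            for sigma in (SIGMA_5436, SIGMA_3654):
                inst = {}
                fold_barrel_permuted(g, 6, 6, sigma, instrument=inst)
                max_conf = max(len(conf_set(sigma, k)) for k in range(1, 7))
                bound = g.n_vertices ** max_conf
                assert max(inst["states_per_level"]) <= bound
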