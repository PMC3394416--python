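import random

import pytest

from barrelfold import (LabeledStructure, ProteinSequence,
                        RunConfig, classify, enumerate_circular_permutations,
                        fold_barrel, make_random_graph, mutate_loops,
                        permutation_landscape, read_annotation,
                        residue_metrics, strand_metrics, structure_to_labeled,
                        write_structure)
from barrelfold.metrics import confusion_metrics


def labeled(residues, states):
    return LabeledStructure(ProteinSequence("t", residues), states)


class TestResidueMetrics:
    def test_perfect_prediction(self):
        truth = labeled("IDIDGGGG", "SSSSLLLL")
        report = residue_metrics(truth, truth)
        assert report.q2 == 100.0
        assert report.mcc == 1.0
        assert report.f_score == 1.0

    def test_hand_computed_confusion(self):
        # TP=3 FP=1 FN=1 TN=5: precision=recall=75%, Q2=80%,
        # MCC = (15-1)/sqrt(4*4*6*6) = 14/24
        report = confusion_metrics(tp=3, fp=1, fn=1, tn=5)
        assert report.specificity == pytest.approx(75.0)
        assert report.sensitivity == pytest.approx(75.0)
        assert report.f_score == pytest.approx(0.75)
        assert report.q2 == pytest.approx(80.0)
        assert report.mcc == pytest.approx(14 / 24)

    def test_all_negative_prediction_degenerate(self):
        pred = labeled("IDIDGGGG", "LLLLLLLL")
        truth = labeled("IDIDGGGG", "SSSSLLLL")
        report = residue_metrics(pred, truth)
        assert report.sensitivity == 0.0
        assert report.mcc == 0.0  # zero-marginal convention

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            residue_metrics(labeled("ID", "SS"), labeled("IDI", "SSS"))

    def test_metric_ranges(self):
        rng = random.Random(0)
        for _ in range(50):
            tp, fp, fn, tn = (rng.randint(0, 20) for _ in range(4))
            if tp + fp + fn + tn == 0:
                continue
            r = confusion_metrics(tp, fp, fn, tn)
            assert 0 <= r.q2 <= 100 and 0 <= r.specificity <= 100
            assert 0 <= r.sensitivity <= 100 and 0 <= r.f_score <= 1
            assert -1 <= r.mcc <= 1


class TestStrandMetrics:
    def test_identical_lists_perfect(self):
        truth = labeled("IDIDGGGGIDID", "SSSSLLLLSSSS")
        report = strand_metrics(truth, truth)
        assert report.specificity == 100.0 and report.sensitivity == 100.0

    def test_one_residue_shift_still_matches(self):
        truth = labeled("G" + "IDIDIDID" + "GGG", "L" + "S" * 8 + "LLL")
        pred = labeled("G" + "IDIDIDID" + "GGG", "SS" * 4 + "LLLL")
        # length-8 strands shifted by one residue overlap by 7/8 > 50%
        report = strand_metrics(pred, truth)
        assert report.sensitivity == 100.0

    def test_seven_of_eight_matched_one_spurious(self):
        report = confusion_metrics(tp=7, fp=1, fn=1, tn=0, level="strands")
        assert report.sensitivity == pytest.approx(87.5)
        assert report.specificity == pytest.approx(87.5)


class TestMutateLoops:
    def test_rate_zero_unchanged(self, planted):
        assert mutate_loops(planted, 0.0).residues == planted.sequence.residues

    def test_mutation_count_and_sites(self, planted):
        mutated = mutate_loops(planted, 0.05, seed=3)
        diffs = [p for p in range(1, planted.sequence.n + 1)
                 if mutated.residues[p - 1] != planted.sequence.residues[p - 1]]
        assert len(diffs) == int(0.05 * planted.sequence.n)
        assert all(planted.states[p - 1] == "L" for p in diffs)

    def test_reproducible_under_seed(self, planted):
        a = mutate_loops(planted, 0.05, seed=9)
        b = mutate_loops(planted, 0.05, seed=9)
        assert a.residues == b.residues

    def test_too_few_loop_positions_warns(self):
        item = labeled("IDIDIDG", "SSSSSSL")
        with pytest.warns(UserWarning):
            mutated = mutate_loops(item, 1.0, seed=0)
        assert mutated.residues[:6] == "IDIDID"
        assert mutated.residues[6] != "G"


class TestClassification:
    def test_no_candidates_is_rejected(self, table40):
        seq = ProteinSequence("neg", "DE" * 40)
        result = classify(seq, table40)
        assert result.decision == "non-TMB"
        assert result.best_structure is None

    def test_planted_barrel_recognized(self, table40, planted):
        result = classify(planted.sequence, table40)
        assert result.decision == "TMB"
        assert result.best_structure.n == 8

    def test_threshold_dominance_and_monotonicity(self, table40, planted):
        cfg = RunConfig(classify_threshold=10 ** 9)
        result = classify(planted.sequence, table40, cfg)
        assert result.decision == "non-TMB"  # structure found, score too low
        assert result.best_structure is not None

    def test_soluble_random_sequence_rejected(self, table40):
        rng = random.Random(5)
        seq = ProteinSequence(
            "sol", "".join(rng.choice("GSPNDEKRQTH") for _ in range(150)))
        assert classify(seq, table40).decision == "non-TMB"


class TestPermutationLandscape:
    def test_row_count_and_identity_consistency(self):
        g = make_random_graph(10, seed=4)
        perms = list(enumerate_circular_permutations(4))
        rows, low = permutation_landscape(g, 4, 4, perms)
        assert len(rows) == len(perms) == 6
        by_sigma = {sig.sigma: e for sig, e in rows}
        direct = fold_barrel(g, 4, 4)
        identity_energy = by_sigma[(1, 2, 3, 4)]
        if direct is None:
            assert identity_energy is None
        else:
            assert identity_energy == pytest.approx(direct.energy)

    def test_zero_window_keeps_only_minimizers(self):
        g = make_random_graph(10, seed=4)
        perms = list(enumerate_circular_permutations(4))
        rows, low = permutation_landscape(g, 4, 4, perms, energy_window=0.0)
        feasible = [e for _s, e in rows if e is not None]
        if feasible:
            e_min = min(feasible)
            assert all(e == pytest.approx(e_min) for _s, e in low)
            assert low


class TestStructureReport:
    def test_write_and_reread_annotation(self, tmp_path, table40, planted):
        result = classify(planted.sequence, table40)
        st = result.best_structure
        tsv = tmp_path / "out.tsv"
        ann = tmp_path / "out.ann"
        write_structure(st, planted.sequence, tsv, ann)
        (back,) = read_annotation(ann)
        assert back.states == structure_to_labeled(st, planted.sequence).states
        lines = tsv.read_text().splitlines()
        assert f"#n\t{st.n}" in lines and f"#S\t{st.S}" in lines

    def test_identity_positions_column(self, tmp_path):
        g = make_random_graph(10, seed=1)
        st = fold_barrel(g, 4, 4)
        assert st is not None
        seq = ProteinSequence("x", "A" * max(v.kappa for v in g.vertices))
        tsv = tmp_path / "s.tsv"
        write_structure(st, seq, tsv)
        rows = [ln.split("\t") for ln in tsv.read_text().splitlines()
                if not ln.startswith("#") and not ln.startswith("strand\t")]
        assert [int(r[3]) for r in rows] == [1, 2, 3, 4]
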