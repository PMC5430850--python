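"""Thermodynamic folding: MFE dynamic program, suboptimal enumeration,
energy evaluation and motif summaries."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from conftest import enumerate_structures
from hairpinforge import (FoldConfig, NucSequence, SecondaryStructure,
                          default_energy_model, describe_motifs,
                          evaluate_energy, fold_mfe, fold_suboptimal)
from hairpinforge.errors import (ConsistencyError, IllegalStructureError,
                                 WrongChemistryError)
from hairpinforge.fold import suboptimal_window, validate_structure


class TestEvaluateEnergy:
    def test_open_chain_scores_zero(self):
        seq = NucSequence("x", "GTACAAAGTAC")
        ss = SecondaryStructure(pair=[0] * 11)
        assert evaluate_energy(seq, ss) == 0.0

    def test_hand_summed_stem_loop(self):
        # 5-bp stem + TGT triloop on CGCGGTGTCCGCG: four stack terms
        # plus the size-3 hairpin penalty, summed term by term from the
        # shipped parameter tables
        model = default_energy_model()
        seq = NucSequence("1LA8", "CGCGGTGTCCGCG")
        pair = [13, 12, 11, 10, 9, 0, 0, 0, 5, 4, 3, 2, 1]
        expected = (model.stack_dg["CG"] + model.stack_dg["GC"]
                    + model.stack_dg["CG"] + model.stack_dg["GG"]
                    + model.hairpin_dg[3])
        got = evaluate_energy(seq, SecondaryStructure(pair=pair))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_mfe_rescoring_is_self_consistent(self, pipeline_folds):
        for name, (seq, ss) in pipeline_folds.items():
            assert evaluate_energy(seq, ss) == pytest.approx(ss.dg,
                                                             abs=1e-9)

    def test_rejects_pseudoknot(self):
        seq = NucSequence("x", "GGGGAAAACCCCAAAA")
        pair = [0] * 16
        # crossing pairs (1,9) and (5,13)
        pair[0], pair[8] = 9, 1
        pair[4], pair[12] = 13, 5
        with pytest.raises(IllegalStructureError):
            evaluate_energy(seq, SecondaryStructure(pair=pair))

    def test_rejects_non_wc_pair(self):
        seq = NucSequence("x", "GGAAAAGG")
        pair = [8, 0, 0, 0, 0, 0, 0, 1]  # G-G
        with pytest.raises(IllegalStructureError):
            evaluate_energy(seq, SecondaryStructure(pair=pair))

    def test_rejects_short_hairpin(self):
        seq = NucSequence("x", "GAATC")
        pair = [5, 0, 0, 0, 1]  # 3-nt loop is minimum; this has 3 -> ok
        validate_structure(seq, SecondaryStructure(pair=pair))
        seq4 = NucSequence("x", "GAAC")
        with pytest.raises(IllegalStructureError):
            validate_structure(seq4,
                               SecondaryStructure(pair=[4, 0, 0, 1]))


class TestFoldMfe:
    def test_poly_a_has_no_pairs(self):
        seq = NucSequence("x", "AAAAAAA")
        ss = fold_mfe(seq)
        assert ss.n_pairs == 0
        assert ss.dg == 0.0

    def test_rna_chemistry_rejected(self):
        with pytest.raises(WrongChemistryError):
            fold_mfe(NucSequence("x", "GCGCAAAGCGC", "RNA"))

    def test_matches_exhaustive_enumeration_on_short_panel(self):
        panel = ["GTACAAAGTAC", "CGCGGTGTCC", "ATATATATAT",
                 "GGGAAACCCAAA", "CCCCAAAA", "AGCUUU".replace("U", "T")]
        for s in panel:
            seq = NucSequence("p", s)
            best = min((e for _, e in enumerate_structures(seq)),
                       default=0.0)
            assert fold_mfe(seq).dg == pytest.approx(best, abs=1e-9)

    def test_closed_fold_returned_when_positive(self):
        # a sequence whose best closed fold is positive: global MFE is
        # the open chain, but the closed variant still reports a fold
        seq = NucSequence("x", "ATAAAAAAT")
        ss_open = fold_mfe(seq)
        ss_closed = fold_mfe(seq, closed=True)
        assert ss_open.n_pairs == 0 and ss_open.dg == 0.0
        assert ss_closed.n_pairs >= 1
        assert ss_closed.dg > 0.0

    def test_appending_bases_never_raises_mfe(self):
        rng = random.Random(3)
        for _ in range(20):
            n = rng.randint(5, 10)
            s = "".join(rng.choice("ACGT") for _ in range(n))
            parent = fold_mfe(NucSequence("a", s)).dg
            child = fold_mfe(NucSequence("b", s + rng.choice("ACGT"))).dg
            assert child <= parent + 1e-9


class TestStructureInvariants:
    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_returned_structures_are_legal(self, seed):
        rng = random.Random(seed)
        n = rng.randint(5, 14)
        s = "".join(rng.choice("ACGT") for _ in range(n))
        seq = NucSequence("h", s)
        ss = fold_mfe(seq)
        validate_structure(seq, ss)  # involution, nesting, WC, loop >= 3
        p = ss.pair
        for i, j in ss.pairs():
            assert p[j - 1] == i
            assert j - i - 1 >= 3 or any(
                p[k] != 0 for k in range(i, j - 1))


class TestSuboptimal:
    def test_window_floor_applies_only_at_nonnegative_mfe(self):
        assert suboptimal_window(-2.0, 5.0) == pytest.approx(-1.9)
        assert suboptimal_window(0.04, 5.0) == pytest.approx(0.54)

    def test_open_tetramer_lists_only_open_chain(self):
        folds = fold_suboptimal(NucSequence("x", "AAAA"))
        assert len(folds) == 1
        assert folds[0].n_pairs == 0

    def test_first_element_is_the_mfe_fold(self):
        seq = NucSequence("1BJH", "GTACAAAGTAC")
        folds = fold_suboptimal(seq)
        mfe = fold_mfe(seq)
        assert folds[0].key() == mfe.key()
        assert folds[0].dg == pytest.approx(mfe.dg, abs=1e-9)

    def test_matches_filtered_enumeration(self):
        rng = random.Random(17)
        for _ in range(6):
            n = rng.randint(8, 10)
            s = "".join(rng.choice("ACGT") for _ in range(n))
            seq = NucSequence("sub", s)
            config = FoldConfig(window_percent=5.0, max_folds=500)
            got = {t.key(): t.dg for t in fold_suboptimal(seq, config=config)}
            all_e = list(enumerate_structures(seq))
            mfe = min(e for _, e in all_e)
            ceiling = suboptimal_window(mfe, 5.0)
            want = {}
            for ss, e in all_e:
                if e <= ceiling + 1e-9:
                    want[ss.key()] = e
            assert set(got) == set(want)
            for k in got:
                assert got[k] == pytest.approx(want[k], abs=1e-9)

    def test_sorted_deduplicated_and_capped(self):
        seq = NucSequence("x", "GCGCGCAAAGCGCGC")
        config = FoldConfig(window_percent=80.0, max_folds=7)
        folds = fold_suboptimal(seq, config=config)
        assert len(folds) <= 7
        keys = [t.key() for t in folds]
        assert len(keys) == len(set(keys))
        assert all(folds[i].dg <= folds[i + 1].dg + 1e-9
                   for i in range(len(folds) - 1))


class TestMotifs:
    def test_published_topologies(self, pipeline_folds):
        _, ss = pipeline_folds["1BJH"]
        m = describe_motifs(ss)
        assert len(m.stems) == 1 and m.stems[0][4] == 4
        assert m.hairpin_loops == [(5, 7, 3)]

        _, ss = pipeline_folds["2M8Y"]
        m = describe_motifs(ss)
        assert m.stems[0][4] == 6
        assert m.hairpin_loops[0][2] == 3

        _, ss = pipeline_folds["2VAH"]
        m = describe_motifs(ss)
        assert m.stems[0][4] == 7
        assert m.hairpin_loops[0][2] == 4

        _, ss = pipeline_folds["2L5K"]
        m = describe_motifs(ss)
        assert sorted(stem[4] for stem in m.stems) == [3, 4]
        assert m.internal_loops == [(3, 3)]
        assert m.hairpin_loops[0][2] == 3

    def test_open_chain_is_all_tail(self):
        m = describe_motifs(SecondaryStructure(pair=[0] * 7))
        assert m.stems == [] and m.hairpin_loops == []
        assert m.tail5 == 7 and m.tail3 == 0

    def test_every_base_in_exactly_one_motif(self, pipeline_folds):
        for name, (seq, ss) in pipeline_folds.items():
            m = describe_motifs(ss)
            n = len(seq)
            counted = m.tail5 + m.tail3 + sum(m.exterior_gaps)
            counted += 2 * sum(stem[4] for stem in m.stems)
            counted += sum(h[2] for h in m.hairpin_loops)
            counted += sum(a + b for a, b in m.internal_loops)
            counted += sum(u for _, u in m.multiloops)
            assert counted == n

    def test_stem_pairs_sum_to_total(self, pipeline_folds):
        for name, (seq, ss) in pipeline_folds.items():
            m = describe_motifs(ss)
            assert sum(stem[4] for stem in m.stems) == ss.n_pairs


class TestFoldConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ConsistencyError):
            FoldConfig(window_percent=-1)
        with pytest.raises(ConsistencyError):
            FoldConfig(max_folds=0)

    def test_max_pair_distance_limits_span(self):
        seq = NucSequence("x", "GCGCAAAAAAAAAAGCGC")
        unlimited = fold_mfe(seq)
        limited = fold_mfe(seq, config=FoldConfig(max_pair_distance=6))
        assert all(j - i <= 6 for i, j in limited.pairs())
        assert limited.dg >= unlimited.dg - 1e-9
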