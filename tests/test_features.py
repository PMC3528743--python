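"""Feature engine: sequence validation, single-feature operations,
catalog construction and the identities that tie them together."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sitransfer.features import (
    build_feature_matrix,
    default_catalog,
    end_asymmetry,
    g_stretch,
    gc_content,
    gc_threshold,
    kmer_count,
    positional_base,
    self_fold,
    stack_dg,
    sum_dg_kmers,
)
from sitransfer.nn_params import DEFAULT_NN_TABLE, NNParameterTable
from sitransfer.records import SequenceError, SirnaRecord, normalize_sequence

from oracles import enumerate_max_pairs

FIXTURE = "UGGAAUCUGUUUAACGGUA"

rna_seq = st.text(alphabet="ACGU", min_size=19, max_size=19)


class TestNormalizeSequence:
    def test_case_and_t_to_u(self):
        assert normalize_sequence("ttggaaucuguuuaacggu") == "UUGGAAUCUGUUUAACGGU"

    @pytest.mark.parametrize("bad", ["UUGGA", "UUGGAAUCUGUUUAACGGN", ""])
    def test_rejects_wrong_length_and_alphabet(self, bad):
        with pytest.raises(SequenceError):
            normalize_sequence(bad)

    def test_record_validates_efficacy_range(self):
        with pytest.raises(ValueError):
            SirnaRecord(id="x", antisense=FIXTURE, efficacy=1.2)


class TestPositionalAndKmer:
    @pytest.mark.parametrize(
        "seq,pos,base,expected",
        [
            ("UGGAAUCUGUUUAACGGUA", 1, "U", 1),
            ("GGGAAUCUGUUUAACGGUA", 1, "U", 0),
            ("UGGAAUCUGUUUAACGGUA", 2, "G", 1),
        ],
    )
    def test_positional_base(self, seq, pos, base, expected):
        assert positional_base(seq, pos, base) == expected

    def test_position_out_of_range(self):
        with pytest.raises(ValueError):
            positional_base(FIXTURE, 20, "A")

    @pytest.mark.parametrize(
        "seq,kmer,window,expected",
        [
            ("U" * 19, "UUUU", (1, 19), 16),  # overlapping occurrences
            ("ACGACGACGACGACGACGA", "UCUG", (1, 19), 0),
            ("UUU", "UU", (1, 3), 2),
        ],
    )
    def test_kmer_count(self, seq, kmer, window, expected):
        assert kmer_count(seq, kmer, window) == expected

    @given(rna_seq, st.integers(min_value=1, max_value=4))
    @settings(max_examples=50, deadline=None)
    def test_kmer_counts_partition_windows(self, seq, k):
        total = sum(
            kmer_count(seq, "".join(t))
            for t in itertools.product("ACGU", repeat=k)
        )
        assert total == 19 - k + 1

    @given(rna_seq)
    @settings(max_examples=50, deadline=None)
    def test_positional_one_hot(self, seq):
        for pos in range(1, 20):
            assert sum(positional_base(seq, pos, b) for b in "ACGU") == 1


class TestGC:
    def test_extremes(self):
        assert gc_content("GC" * 9 + "G") == 1.0
        assert gc_content("AU" * 9 + "A") == 0.0

    def test_hand_counted_fixture(self):
        # UGGAAUCUGUUUAACGGUA has 7 G/C of 19
        assert gc_content(FIXTURE) == pytest.approx(7 / 19)
        assert gc_threshold(FIXTURE, 0.55, "<") == 1
        assert gc_threshold(FIXTURE, 0.45, ">") == 0

    @given(rna_seq, st.sampled_from([0.35, 0.45, 0.55, 0.65, 0.75]))
    @settings(max_examples=50, deadline=None)
    def test_indicator_consistent_with_real_value(self, seq, t):
        gc = gc_content(seq)
        assert gc_threshold(seq, t, "<") == int(gc < t)
        assert gc_threshold(seq, t, ">") == int(gc > t)


class TestThermo:
    def test_window_of_two_is_single_lookup(self):
        assert stack_dg(FIXTURE, (1, 2)) == DEFAULT_NN_TABLE["UG"]

    def test_full_window_hand_summed(self):
        # 18 stacks of the fixture summed by hand from the parameter table
        assert stack_dg(FIXTURE, (1, 19)) == pytest.approx(-34.08)

    def test_strict_additivity_over_partition(self):
        full = stack_dg(FIXTURE, (1, 19))
        # stacks of [1,10] and [10,19] partition the 18 stacks exactly
        assert full == pytest.approx(
            stack_dg(FIXTURE, (1, 10)) + stack_dg(FIXTURE, (10, 19))
        )

    def test_sum_of_stack_decomposition(self):
        total = sum(
            DEFAULT_NN_TABLE[FIXTURE[i : i + 2]] for i in range(18)
        )
        assert stack_dg(FIXTURE, (1, 19)) == pytest.approx(total)

    def test_end_asymmetry_definition_and_hand_value(self):
        val = end_asymmetry(FIXTURE, (1, 2), (18, 19))
        assert val == pytest.approx(
            stack_dg(FIXTURE, (1, 2)) - stack_dg(FIXTURE, (18, 19))
        )
        # UG (-2.11) minus UA (-1.33) by hand
        assert val == pytest.approx(-0.78)

    def test_symmetric_windows_cancel(self):
        assert end_asymmetry(FIXTURE, (3, 6), (3, 6)) == 0.0

    def test_sum_dg4_window_count(self):
        # 16 tetramer windows, each contributing 3 stacks
        manual = sum(stack_dg(FIXTURE, (i, i + 3)) for i in range(1, 17))
        assert sum_dg_kmers(FIXTURE, 4) == pytest.approx(manual)

    def test_missing_stack_entry_raises(self):
        table = NNParameterTable()
        broken = dict(table.stack_dG)
        with pytest.raises(ValueError):
            NNParameterTable({k: v for k, v in broken.items() if k != "AA"})


class TestSelfFold:
    def test_unpairable_sequence(self):
        pairs, vec = self_fold("A" * 19)
        assert pairs == 0
        assert not vec.any()

    def test_small_hairpin(self):
        pairs, vec = self_fold("GGGAAACCC")
        assert pairs == enumerate_max_pairs("GGGAAACCC") == 3
        assert vec.sum() == 6

    def test_dp_matches_enumeration_randomized(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 13))
            seq = "".join(rng.choice(list("ACGU"), n))
            assert self_fold(seq)[0] == enumerate_max_pairs(seq), seq

    def test_traceback_pair_count_consistent(self, rng):
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGU"), 19))
            pairs, vec = self_fold(seq)
            assert vec.sum() == 2 * pairs


class TestGStretch:
    @pytest.mark.parametrize(
        "seq,min_len,expected",
        [
            ("AGGGA" + "A" * 14, 3, 1),
            ("AGGAGGAGGAGGAGGAGGA", 3, 0),
            ("GGG" + "A" * 16, 4, 0),
        ],
    )
    def test_examples(self, seq, min_len, expected):
        assert g_stretch(seq, min_len) == expected


class TestCatalog:
    def test_size_and_unique_names(self):
        cat = default_catalog()
        assert len(cat) == 146
        assert len(set(cat.names)) == len(cat)

    def test_empty_records_gives_empty_matrix(self):
        fm = build_feature_matrix([], default_catalog())
        assert fm.values.shape == (0, 146)

    def test_matrix_deterministic_and_consistent(self):
        recs = [
            SirnaRecord(id=f"r{i}", antisense=s)
            for i, s in enumerate(
                [FIXTURE, "GCGCGCGCGCGCGCGCGCG", "AUAUAUAUAUAUAUAUAUA"]
            )
        ]
        cat = default_catalog()
        fm1 = build_feature_matrix(recs, cat)
        fm2 = build_feature_matrix(recs, cat)
        assert np.array_equal(fm1.values, fm2.values)
        # every cell equals the single-feature operation applied directly
        for i, rec in enumerate(recs):
            for d in cat.definitions:
                assert fm1.values[i, d.feature_id] == d.compute(rec.antisense)

    def test_extra_kmers_extend_catalog(self):
        cat = default_catalog(extra_kmers=["UCUG"])
        j = cat.index_of("UCUG in NT[1..19]")
        assert cat.definitions[j].compute("UCUG" + "A" * 15) == 1
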