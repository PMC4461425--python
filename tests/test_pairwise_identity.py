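import numpy as np
import pytest
from hypothesis import given, strategies as st

from otubench.amplicon_io import AlignedSeqRecord
from otubench.errors import AlignmentFormatError, UndefinedIdentityError
from otubench.pairwise_identity import (
    DEFAULT_SCORING,
    AlignedPair,
    AlignmentStats,
    GapDefinition,
    IdentityConfig,
    ScoringScheme,
    TerminalPolicy,
    alignment_stats,
    distance_matrix,
    distance_matrix_from_msa,
    divergence,
    global_align,
    global_align_score,
    identity,
    msa_pair_identity,
    pair_divergence,
    write_phylip_lower,
)

from conftest import random_seq
from oracles import oracle_best_score, oracle_identity, score_gapped_pair

EACH_COUNT = IdentityConfig(GapDefinition.EACH_GAP, TerminalPolicy.COUNT)
EACH_EXCL = IdentityConfig(GapDefinition.EACH_GAP, TerminalPolicy.EXCLUDE)
ONE_COUNT = IdentityConfig(GapDefinition.ONE_GAP, TerminalPolicy.COUNT)
NO_GAPS = IdentityConfig(GapDefinition.NO_GAPS, TerminalPolicy.COUNT)


class TestAlignedPair:
    def test_unequal_lengths_rejected(self):
        with pytest.raises(AlignmentFormatError):
            AlignedPair("ACGT", "ACG")

    def test_double_gap_column_rejected(self):
        with pytest.raises(AlignmentFormatError):
            AlignedPair("A-GT", "A-GT")

    def test_ungapping_recovers_inputs(self):
        pair = AlignedPair("AC-GT", "ACCGT")
        assert pair.ungapped_a() == "ACGT"
        assert pair.ungapped_b() == "ACCGT"


class TestGlobalAlign:
    def test_identical_sequences(self):
        pair = global_align("ACGTACGT", "ACGTACGT")
        stats = alignment_stats(pair)
        assert stats.M == 8 and stats.X == 0
        assert stats.C_int == stats.C_term == 0

    def test_small_gap_case_matches_oracle(self):
        # under the default end-gap-cheap scoring the optimum trades the
        # internal gap for a 1-column terminal gap; verified exhaustively
        pair = global_align("ACGT", "AGT")
        score = score_gapped_pair(pair.gapped_a, pair.gapped_b,
                                  DEFAULT_SCORING)
        assert score == oracle_best_score("ACGT", "AGT", DEFAULT_SCORING)
        stats = alignment_stats(pair)
        assert stats.C_int + stats.C_term == 1

    def test_small_gap_case_full_global(self):
        # with end gaps penalised like internal ones the classic single
        # internal gap column is optimal: M=3, X=0
        scoring = ScoringScheme.full_global()
        pair = global_align("ACGT", "AGT", scoring)
        stats = alignment_stats(pair)
        assert (stats.M, stats.X, stats.C_int + stats.C_term) == (3, 0, 1)
        assert score_gapped_pair(pair.gapped_a, pair.gapped_b, scoring) == \
            oracle_best_score("ACGT", "AGT", scoring)

    def test_prefix_pair_terminal_run(self):
        pair = global_align("ACGTACGT", "ACGT")
        stats = alignment_stats(pair)
        assert stats.M == 4 and stats.X == 0
        assert stats.C_term == 4 and stats.R_term == 1 and stats.C_int == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    def test_deterministic(self):
        a, b = "ACGTTGCA", "ACGTGCAA"
        first = global_align(a, b)
        for _ in range(5):
            assert global_align(a, b) == first

    def test_exhaustive_enumeration_oracle(self, rng):
        # scores agree with brute-force enumeration of every alignment,
        # and the reported alignment achieves the optimal score
        for _ in range(40):
            a = random_seq(rng, int(rng.integers(1, 7)))
            b = random_seq(rng, int(rng.integers(1, 7)))
            best = oracle_best_score(a, b, DEFAULT_SCORING)
            assert global_align_score(a, b) == pytest.approx(best)
            pair = global_align(a, b)
            assert score_gapped_pair(pair.gapped_a, pair.gapped_b,
                                     DEFAULT_SCORING) == pytest.approx(best)


class TestAlignmentStats:
    @pytest.mark.parametrize("a,b,expected", [
        ("AC-GT", "ACCGT", dict(M=4, X=0, C_int=1, R_int=1, C_term=0)),
        ("ACGT----", "ACGTACGT", dict(M=4, X=0, C_int=0, C_term=4, R_term=1)),
        ("A--T", "AGCT", dict(M=2, X=0, C_int=2, R_int=1)),
    ])
    def test_hand_counts(self, a, b, expected):
        stats = alignment_stats(AlignedPair(a, b))
        for key, value in expected.items():
            assert getattr(stats, key) == value, key

    def test_n_as_match_configurable(self):
        pair = AlignedPair("ANGT", "ACGT")
        assert alignment_stats(pair).M == 4
        stats = alignment_stats(pair, n_as_match=False)
        assert stats.M == 3 and stats.X == 1

    def test_column_conservation(self, rng):
        for _ in range(20):
            a = random_seq(rng, int(rng.integers(5, 40)))
            b = random_seq(rng, int(rng.integers(5, 40)))
            pair = global_align(a, b)
            stats = alignment_stats(pair)
            assert (stats.M + stats.X + stats.C_int + stats.C_term
                    == len(pair.gapped_a))
            assert stats.R_int <= stats.C_int
            assert stats.R_term <= stats.C_term


class TestIdentity:
    def test_worked_example(self):
        # 400-column alignment: 390 matches, 6 mismatches, one internal
        # 4-nt gap run
        stats = AlignmentStats(M=390, X=6, C_int=4, R_int=1,
                               C_term=0, R_term=0)
        assert identity(stats, NO_GAPS) == pytest.approx(390 / 396)
        assert identity(stats, ONE_COUNT) == pytest.approx(390 / 397)
        assert identity(stats, EACH_COUNT) == pytest.approx(390 / 400)

    def test_identical_sequences_all_definitions(self):
        stats = alignment_stats(global_align("ACGTAC", "ACGTAC"))
        for definition in GapDefinition:
            for policy in TerminalPolicy:
                cfg = IdentityConfig(definition, policy)
                assert identity(stats, cfg) == 1.0

    def test_terminal_gap_mechanism(self):
        stats = alignment_stats(global_align("ACGTACGT", "ACGT"))
        assert identity(stats, EACH_COUNT) == pytest.approx(0.5)
        assert identity(stats, EACH_EXCL) == 1.0
        assert identity(stats, NO_GAPS) == 1.0

    def test_undefined_identity(self):
        stats = AlignmentStats(M=0, X=0, C_int=0, R_int=0, C_term=8, R_term=2)
        with pytest.raises(UndefinedIdentityError):
            identity(stats, EACH_COUNT)

    def test_divergence_complement(self):
        stats = AlignmentStats(M=95, X=5, C_int=0, R_int=0,
                               C_term=0, R_term=0)
        assert divergence(stats, NO_GAPS) == pytest.approx(0.05)

    @given(m=st.integers(1, 500), x=st.integers(0, 100),
           r_int=st.integers(0, 20), extra_int=st.integers(0, 60),
           r_term=st.integers(0, 2), extra_term=st.integers(0, 60))
    def test_definition_ordering(self, m, x, r_int, extra_int, r_term,
                                 extra_term):
        c_int = r_int + (extra_int if r_int else 0)
        c_term = r_term + (extra_term if r_term else 0)
        stats = AlignmentStats(M=m, X=x, C_int=c_int, R_int=r_int,
                               C_term=c_term, R_term=r_term)
        for policy in TerminalPolicy:
            no = identity(stats, IdentityConfig(GapDefinition.NO_GAPS, policy))
            one = identity(stats, IdentityConfig(GapDefinition.ONE_GAP, policy))
            each = identity(stats, IdentityConfig(GapDefinition.EACH_GAP,
                                                  policy))
            assert no >= one >= each
        for definition in GapDefinition:
            count = identity(stats, IdentityConfig(definition,
                                                   TerminalPolicy.COUNT))
            excl = identity(stats, IdentityConfig(definition,
                                                  TerminalPolicy.EXCLUDE))
            assert excl >= count

    def test_symmetry(self, rng):
        for _ in range(10):
            a = random_seq(rng, int(rng.integers(20, 60)))
            b = random_seq(rng, int(rng.integers(20, 60)))
            for cfg in (NO_GAPS, ONE_COUNT, EACH_COUNT):
                assert pair_divergence(a, b, cfg) == \
                    pytest.approx(pair_divergence(b, a, cfg))

    def test_gap_free_alignment_definitions_coincide(self):
        stats = AlignmentStats(M=37, X=3, C_int=0, R_int=0,
                               C_term=0, R_term=0)
        values = {identity(stats, IdentityConfig(d, p))
                  for d in GapDefinition for p in TerminalPolicy}
        assert len(values) == 1

    def test_against_verbal_definition_oracle(self, rng):
        for _ in range(15):
            a = random_seq(rng, int(rng.integers(10, 50)))
            b = random_seq(rng, int(rng.integers(10, 50)))
            pair = global_align(a, b)
            for definition in GapDefinition:
                for policy in TerminalPolicy:
                    cfg = IdentityConfig(definition, policy)
                    expect = oracle_identity(pair.gapped_a, pair.gapped_b,
                                             definition.value, policy.value)
                    got = identity(alignment_stats(pair), cfg)
                    assert got == pytest.approx(expect)


class TestMsaPairIdentity:
    def test_identical_rows_with_shared_gap(self):
        r1 = AlignedSeqRecord("a", "AC-GT")
        r2 = AlignedSeqRecord("b", "AC-GT")
        assert msa_pair_identity(r1, r2, EACH_COUNT) == 1.0

    def test_consistent_with_pairwise_case(self):
        r1 = AlignedSeqRecord("a", "AC-GT")
        r2 = AlignedSeqRecord("b", "ACCGT")
        got = msa_pair_identity(r1, r2, EACH_COUNT)
        stats = alignment_stats(AlignedPair("AC-GT", "ACCGT"))
        assert got == identity(stats, EACH_COUNT)

    def test_leading_gap_terminal_rule(self):
        r1 = AlignedSeqRecord("a", "A---T")
        r2 = AlignedSeqRecord("b", "-ACGT")
        from otubench.pairwise_identity import msa_pair
        stats = alignment_stats(msa_pair(r1, r2))
        # row 2's leading run is terminal; row 1's 3-column run is internal
        assert stats.C_term == 1 and stats.R_term == 1
        assert stats.C_int == 3 and stats.R_int == 1

    def test_ragged_rows_rejected(self):
        with pytest.raises(AlignmentFormatError):
            msa_pair_identity(AlignedSeqRecord("a", "ACGT-"),
                              AlignedSeqRecord("b", "ACGT"), EACH_COUNT)


class TestDistanceMatrix:
    def test_identical_pair(self):
        dmat = distance_matrix(["ACGTACGTAA", "ACGTACGTAA"], EACH_COUNT)
        assert np.allclose(dmat, 0.0)

    def test_shape_and_symmetry(self, rng):
        seqs = [random_seq(rng, 30) for _ in range(5)]
        dmat = distance_matrix(seqs, EACH_COUNT)
        assert dmat.shape == (5, 5)
        assert np.allclose(dmat, dmat.T)
        assert np.allclose(np.diag(dmat), 0.0)

    def test_definition_ordering_elementwise(self, rng):
        seqs = [random_seq(rng, int(rng.integers(25, 45))) for _ in range(5)]
        d_no = distance_matrix(seqs, NO_GAPS)
        d_one = distance_matrix(seqs, ONE_COUNT)
        d_each = distance_matrix(seqs, EACH_COUNT)
        assert (d_each >= d_one - 1e-12).all()
        assert (d_one >= d_no - 1e-12).all()

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            distance_matrix(["ACGT"], EACH_COUNT)

    def test_msa_matrix_agrees_with_rowwise(self, rng):
        rows = [AlignedSeqRecord(f"r{i}", g) for i, g in enumerate(
            ["ACGT--ACGTAA", "ACGTGGACGT--", "AC-TGGAC-TAA", "ACGTGGAC--AA"])]
        for cfg in (NO_GAPS, ONE_COUNT, EACH_COUNT, EACH_EXCL):
            dmat = distance_matrix_from_msa(rows, cfg)
            for i in range(4):
                for j in range(i + 1, 4):
                    expect = 1.0 - msa_pair_identity(rows[i], rows[j], cfg)
                    assert dmat[i, j] == pytest.approx(expect)

    def test_phylip_export(self, tmp_path):
        dmat = np.array([[0.0, 0.1], [0.1, 0.0]])
        path = tmp_path / "dist.phylip"
        write_phylip_lower(dmat, ["a", "b"], path)
        lines = path.read_text().splitlines()
        assert lines[0] == "2"
        assert lines[2].startswith("b\t0.100000")
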