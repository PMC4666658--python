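import math
import random

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from orthoseek.align import (
    ScoringScheme,
    build_pssm,
    estimate_evalue,
    load_matrix,
    local_align,
    percent_identity,
    profile_search,
)
from orthoseek.seqio import AlignmentHit, ProteinDatabase, SequenceRecord

from oracle import oracle_align


def rec(acc, seq):
    return SequenceRecord(acc, seq)


def _aa_index(aa):
    from orthoseek.align import _AA_INDEX
    return _AA_INDEX[aa]


def blosum_fn(name):
    mat = substitution_matrices.load(name)

    def fn(a, b):
        if a == "X" or b == "X":
            return 0.0
        return float(mat[a, b])

    return fn


class TestLocalAlign:
    def test_self_alignment_is_full_identity(self):
        hit = local_align(rec("a", "MKVLAT"), rec("b", "MKVLAT"))
        assert hit.identity_pct == 100.0
        assert hit.aln_length == 6
        assert (hit.q_start, hit.q_end, hit.s_start, hit.s_end) == (1, 6, 1, 6)

    def test_textbook_linear_gap_alignment(self):
        # Classic BLOSUM50 local alignment with linear gap penalty 8.
        scheme = ScoringScheme(matrix_name="BLOSUM50", gap_open=8, gap_extend=8)
        hit = local_align(rec("q", "HEAGAWGHEE"), rec("s", "PAWHEAE"), scheme)
        expected = oracle_align("HEAGAWGHEE", "PAWHEAE", blosum_fn("BLOSUM50"), 8, 8)
        assert hit.raw_score == expected[0] == 28.0
        assert (hit.aligned_query, hit.aligned_subject) == (expected[1], expected[2])

    def test_no_positive_pair_returns_none(self):
        # G vs P scores -2 in BLOSUM62; nothing positive to seed an alignment.
        assert local_align(rec("a", "GGG"), rec("b", "PPP")) is None

    def test_spans_match_ungapped_lengths(self):
        hit = local_align(rec("a", "MKVAAAWCDEFG"), rec("b", "MKVWCDEFG"))
        q_span = hit.q_end - hit.q_start + 1
        s_span = hit.s_end - hit.s_start + 1
        assert q_span == sum(1 for c in hit.aligned_query if c != "-")
        assert s_span == sum(1 for c in hit.aligned_subject if c != "-")
        assert len(hit.aligned_query) == len(hit.aligned_subject) == hit.aln_length

    @pytest.mark.parametrize("gaps", [(11, 1), (8, 8), (5, 2)])
    def test_matches_bruteforce_oracle_on_random_short_pairs(self, gaps):
        """Engine equals an exhaustive DP oracle on short 4-letter sequences."""
        rng = random.Random(1234)
        scheme = ScoringScheme(gap_open=gaps[0], gap_extend=gaps[1])
        fn = blosum_fn("BLOSUM62")
        alpha = "ACDE"
        for _ in range(150):
            q = "".join(rng.choice(alpha) for _ in range(rng.randint(1, 12)))
            s = "".join(rng.choice(alpha) for _ in range(rng.randint(1, 12)))
            got = local_align(rec("q", q), rec("s", s), scheme)
            exp = oracle_align(q, s, fn, *gaps)
            if exp is None:
                assert got is None
            else:
                assert got.raw_score == exp[0]
                assert (got.aligned_query, got.aligned_subject) == (exp[1], exp[2])

    def test_score_symmetric_for_symmetric_matrix(self):
        rng = random.Random(7)
        for _ in range(30):
            q = "".join(rng.choice("ACDEFGHIK") for _ in range(rng.randint(2, 15)))
            s = "".join(rng.choice("ACDEFGHIK") for _ in range(rng.randint(2, 15)))
            h1 = local_align(rec("q", q), rec("s", s))
            h2 = local_align(rec("s", s), rec("q", q))
            assert (h1 is None) == (h2 is None)
            if h1 is not None:
                assert h1.raw_score == h2.raw_score

    def test_x_scores_zero(self):
        mat = load_matrix("BLOSUM62")
        assert np.all(mat[20, :] == 0) and np.all(mat[:, 20] == 0)


class TestPercentIdentity:
    def test_exact_match(self):
        hit = local_align(rec("a", "AWGHE"), rec("b", "AWGHE"))
        assert percent_identity(hit) == 100.0

    def test_gap_columns_count_in_denominator(self):
        hit = AlignmentHit("q", "s", 0.0, 5, 1, 5, 1, 4, 10, 10, 1e-5,
                           aligned_query="AWGHE", aligned_subject="AW-HE")
        assert percent_identity(hit) == 80.0

    def test_random_pairs_agree_with_column_count(self):
        rng = random.Random(99)
        for _ in range(50):
            q = "".join(rng.choice("ACDEFGHIKLMN") for _ in range(rng.randint(5, 30)))
            s = "".join(rng.choice("ACDEFGHIKLMN") for _ in range(rng.randint(5, 30)))
            hit = local_align(rec("q", q), rec("s", s))
            if hit is None:
                continue
            ident = sum(
                a == b and a != "-"
                for a, b in zip(hit.aligned_query, hit.aligned_subject)
            )
            assert percent_identity(hit) == pytest.approx(100 * ident / hit.aln_length)

    def test_zero_length_errors(self):
        hit = AlignmentHit("q", "s", 0.0, 0, 1, 1, 1, 1, 0, 0, 1.0)
        with pytest.raises(ValueError):
            percent_identity(hit)


class TestEvalue:
    def test_closed_form(self):
        scheme = ScoringScheme(karlin_K=0.041, karlin_lambda=0.267)
        expected = 0.041 * 100 * 10000 * math.exp(-0.267 * 100)
        assert estimate_evalue(100, 100, 10000, scheme) == pytest.approx(expected)

    def test_linear_in_database_size(self):
        e1 = estimate_evalue(50, 100, 10000)
        e2 = estimate_evalue(50, 100, 20000)
        assert e2 == pytest.approx(2 * e1)

    def test_monotone_decreasing_in_score(self):
        evs = [estimate_evalue(s, 100, 10000) for s in range(1, 200, 10)]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_nonpositive_score_capped(self):
        scheme = ScoringScheme()
        assert estimate_evalue(-5, 100, 1000, scheme) == scheme.karlin_K * 100 * 1000


class TestPSSM:
    def test_background_frequencies_give_zero_scores(self):
        # 19 hits supply the 19 non-reference residues once each; with the
        # reference residue included the column is uniform, matching a
        # uniform background, so every log-odds score is 0.
        ref = rec("r", "A")
        hits = [
            AlignmentHit("r", f"h{i}", 0.0, 1, 1, 1, 1, 1, 5, 5, 1e-9,
                         aligned_query="A", aligned_subject=aa)
            for i, aa in enumerate("CDEFGHIKLMNPQRSTVWY")
        ]
        pssm = build_pssm(ref, hits, pseudocount_weight=2.0,
                          background=np.full(20, 0.05))
        assert np.allclose(pssm.columns, 0.0, atol=1e-12)

    def test_single_sequence_small_beta_limit(self):
        # One observed 'A' column: as beta -> 0 the log-odds tends to
        # log2(1 / p_A) = log2(20) under a uniform background.
        ref = rec("r", "A")
        self_hit = AlignmentHit("r", "r", 100.0, 1, 1, 1, 1, 1, 4, 4, 1e-9,
                                aligned_query="A", aligned_subject="A")
        pssm = build_pssm(ref, [self_hit], pseudocount_weight=1e-9,
                          background=np.full(20, 0.05))
        assert pssm.columns[0, 0] == pytest.approx(math.log2(20), abs=1e-5)

    def test_uncovered_columns_fall_back_to_matrix_row(self):
        pssm = build_pssm(rec("r", "W"), [], pseudocount_weight=5.0)
        mat = load_matrix("BLOSUM62")
        scheme = ScoringScheme()
        expected = mat[_aa_index("W"), :20] * scheme.karlin_lambda / math.log(2)
        assert np.allclose(pssm.columns[0], expected)

    def test_consensus_length_equals_reference_length(self, small_family):
        db, _, truth, _ = small_family
        ref = db[truth.reference]
        member = db[sorted(truth.homologs)[0]]
        hit = local_align(ref, member)
        pssm = build_pssm(ref, [hit])
        assert pssm.consensus_length == len(ref)

    def test_zero_beta_with_unobserved_residue_errors(self):
        ref = rec("r", "AA")
        hit = AlignmentHit("r", "h", 100.0, 2, 1, 2, 1, 2, 8, 8, 1e-9,
                           aligned_query="AA", aligned_subject="AA")
        with pytest.raises(ValueError, match="beta"):
            build_pssm(ref, [hit], pseudocount_weight=0.0)


class TestProfileSearch:
    def test_reference_is_top_hit_in_its_own_db(self, small_family):
        db, _, truth, _ = small_family
        ref = db[truth.reference]
        pssm = build_pssm(ref, [])
        hits = profile_search(pssm, db)
        assert hits[0].subject_id == truth.reference

    def test_empty_db_gives_empty_list(self):
        pssm = build_pssm(rec("r", "MKVLAT"), [])
        assert profile_search(pssm, ProteinDatabase(records=[], name="e")) == []

    def test_planted_family_ranks_above_decoys(self, small_family):
        db, _, truth, _ = small_family
        ref = db[truth.reference]
        pssm = build_pssm(ref, [])
        order = [h.subject_id for h in profile_search(pssm, db)]
        family = truth.expected_members | set(truth.paralogs)
        family_ranks = [order.index(a) for a in family if a in order]
        decoy_ranks = [order.index(a) for a in truth.decoys if a in order]
        assert max(family_ranks) < min(decoy_ranks)

    def test_sorted_by_evalue(self, small_family):
        db, _, truth, _ = small_family
        hits = profile_search(build_pssm(db[truth.reference], []), db)
        evs = [h.evalue for h in hits]
        assert evs == sorted(evs)
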