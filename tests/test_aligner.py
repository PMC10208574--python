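from functools import lru_cache

import numpy as np
import pytest
from Bio import Align
from hypothesis import given, settings, strategies as st

from cretrace.aligner import (
    AlphabetError,
    CalibrationError,
    LocalAlignment,
    ScoringScheme,
    alignment_evalue,
    karlin_lambda,
    percent_identity,
    waterman_eggert,
)

DNA = st.text(alphabet="ACGT", min_size=1, max_size=40)


def brute_force_best_score(q, t, match=5, mismatch=-4, gap_open=16, gap_extend=4):
    """Best local alignment score by exhaustive recursion over end states.

    Independent top-down formulation: an alignment is a path of columns
    ending gaplessly; state (i, j, op) is the best score of any alignment
    whose last column consumes q[i-1]/t[j-1] with operation op
    (0 = substitution, 1 = gap in query, 2 = gap in template).
    """
    NEG = -(10**9)

    @lru_cache(maxsize=None)
    def end(i, j, op):
        if op == 0:
            s = match if q[i - 1] == t[j - 1] else mismatch
            prev = 0
            if i > 1 and j > 1:
                prev = max(0, end(i - 1, j - 1, 0), end(i - 1, j - 1, 1), end(i - 1, j - 1, 2))
            return s + prev
        if op == 1:  # gap in query consumes t[j-1]
            if j <= 1 or i < 1:
                return NEG
            return max(end(i, j - 1, 0) - gap_open, end(i, j - 1, 1) - gap_extend)
        if i <= 1 or j < 1:
            return NEG
        return max(end(i - 1, j, 0) - gap_open, end(i - 1, j, 2) - gap_extend)

    best = 0
    for i in range(1, len(q) + 1):
        for j in range(1, len(t) + 1):
            best = max(best, end(i, j, 0))
    return best


@pytest.fixture(scope="module")
def biopython_aligner():
    pa = Align.PairwiseAligner(
        mode="local",
        match_score=5,
        mismatch_score=-4,
        open_gap_score=-16,
        extend_gap_score=-4,
    )
    return pa


class TestKnownAlignments:
    def test_self_alignment_of_60nt(self, scheme):
        s = "ACGTTGCAAC" * 6
        (aln,) = waterman_eggert(s, s, scheme)
        assert (aln.score, aln.n_columns, aln.pct_identity) == (300, 60, 100.0)

    def test_single_mismatch_spans_all_columns(self, scheme):
        (aln,) = waterman_eggert("ACGTACGT", "ACGTTCGT", scheme)
        assert aln.score == 31  # 7 matches - 1 mismatch
        assert aln.n_columns == 8
        assert aln.n_identical == 7
        assert percent_identity(aln) == pytest.approx(87.5)

    def test_all_negative_pairs_give_no_alignment(self, scheme):
        assert waterman_eggert("AAAA", "CCCC", scheme) == []

    def test_gap_cost_is_open_plus_extensions(self, scheme):
        q = "ACGTACGTAC" + "TGCATGCATG"
        # 20 matches bridged by a gap: open charges the first position,
        # extend each additional one
        (a1,) = waterman_eggert(q, "ACGTACGTAC" + "C" + "TGCATGCATG", scheme)
        assert a1.score == 100 - 16
        (a2,) = waterman_eggert(q, "ACGTACGTAC" + "CC" + "TGCATGCATG", scheme)
        assert a2.score == 100 - 16 - 4
        assert "1D" in a1.cigar() and "2D" in a2.cigar()

    def test_n_is_never_identical(self, scheme):
        (aln,) = waterman_eggert("ACGTACGTACGTN", "ACGTACGTACGTN", scheme)
        assert aln.n_identical == 12

    def test_non_alphabet_character_rejected(self, scheme):
        with pytest.raises(AlphabetError):
            waterman_eggert("ACGT!", "ACGT", scheme)


class TestOracles:
    def test_matches_exhaustive_enumeration_to_length_8(self, scheme, rng):
        for _ in range(150):
            q = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 9)))
            t = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 9)))
            ours = waterman_eggert(q, t, scheme)
            got = ours[0].score if ours else 0
            assert got == brute_force_best_score(q, t), (q, t)

    def test_matches_biopython_on_longer_pairs(self, scheme, rng, biopython_aligner):
        for _ in range(120):
            q = "".join(rng.choice(list("ACGT"), size=rng.integers(10, 80)))
            t = "".join(rng.choice(list("ACGT"), size=rng.integers(10, 80)))
            ours = waterman_eggert(q, t, scheme)
            got = ours[0].score if ours else 0
            assert got == biopython_aligner.score(q, t), (q, t)


class TestProperties:
    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(DNA, DNA)
    def test_score_symmetry(self, q, t):
        a = waterman_eggert(q, t)
        b = waterman_eggert(t, q)
        assert (a[0].score if a else 0) == (b[0].score if b else 0)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(DNA, DNA, st.text(alphabet="ACGT", min_size=0, max_size=20))
    def test_appending_context_never_lowers_score(self, q, t, extra):
        base = waterman_eggert(q, t)
        ext = waterman_eggert(extra + q + extra, t)
        assert (ext[0].score if ext else 0) >= (base[0].score if base else 0)

    def test_waterman_eggert_alignments_do_not_share_pairs(self, rng, scheme):
        for _ in range(20):
            q = "".join(rng.choice(list("ACGT"), size=60))
            t = "".join(rng.choice(list("ACGT"), size=60))
            alns = waterman_eggert(q, t, scheme, k=4)
            seen = set()
            scores = [a.score for a in alns]
            assert scores == sorted(scores, reverse=True)
            for a in alns:
                pairs = {(c[0], c[1]) for c in a.columns if c[0] is not None and c[1] is not None}
                assert not (pairs & seen)
                seen |= pairs

    def test_alignment_endpoints_are_gapless(self, rng, scheme):
        for _ in range(20):
            q = "".join(rng.choice(list("ACGT"), size=50))
            t = "".join(rng.choice(list("ACGT"), size=50))
            for a in waterman_eggert(q, t, scheme, k=3):
                assert a.columns[0][0] is not None and a.columns[0][1] is not None
                assert a.columns[-1][0] is not None and a.columns[-1][1] is not None
                assert a.score > 0


class TestEvalue:
    @staticmethod
    def _aln(score):
        return LocalAlignment((0, 10), (0, 10), tuple((i, i) for i in range(10)), score, 10)

    def test_monotone_decreasing_in_score(self):
        assert alignment_evalue(self._aln(100), 400, 400) < alignment_evalue(
            self._aln(80), 400, 400
        )

    def test_linear_in_search_space(self):
        e1 = alignment_evalue(self._aln(90), 400, 400)
        e2 = alignment_evalue(self._aln(90), 800, 400)
        assert e2 == pytest.approx(2 * e1)

    def test_lambda_solves_transcendental_equation(self, scheme):
        lam = karlin_lambda(scheme, gc_fraction=0.4)
        # independent bisection on sum p_i p_j exp(lam * s_ij) = 1
        p = {"A": 0.3, "T": 0.3, "G": 0.2, "C": 0.2}

        def f(x):
            return (
                sum(
                    p[a] * p[b] * np.exp(x * (5 if a == b else -4))
                    for a in "ACGT"
                    for b in "ACGT"
                )
                - 1.0
            )

        lo, hi = 1e-9, 2.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
        assert lam == pytest.approx((lo + hi) / 2, abs=1e-6)

    def test_positive_expected_score_fails_calibration(self):
        table = np.full((15, 15), 5, dtype=np.int32)
        scheme = ScoringScheme(substitution_table=table)
        with pytest.raises(CalibrationError):
            karlin_lambda(scheme)
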