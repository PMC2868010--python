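"""Pairwise match scoring, alignment scores and the SMS decomposition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dfmalign.errors import ValidationError
from dfmalign.scoring import (
    Alignment,
    ScoreParams,
    alignment_score,
    extract_submatrices,
    pms,
    rel_diff,
    score_alignment,
    sms_profile,
)

DEFAULTS = ScoreParams()


def brute_force_score(fa, fb, pairs, params=DEFAULTS):
    """Independent oracle: explicit double loop over column pairs."""
    total = 0.0
    for i in range(len(pairs)):
        for j in range(i + 1, len(pairs)):
            ai, bi = pairs[i]
            aj, bj = pairs[j]
            total += pms(fa.matrix[ai, aj], fb.matrix[bi, bj], params)
    return total


class TestAlignment:
    def test_rejects_non_monotone_pairs(self):
        with pytest.raises(ValidationError):
            Alignment([(0, 1), (1, 1)])
        with pytest.raises(ValidationError):
            Alignment([(2, 0), (1, 1)])
        with pytest.raises(ValidationError):
            Alignment([(-1, 0)])

    def test_swapped_roundtrip(self):
        aln = Alignment([(0, 2), (3, 5)])
        assert aln.swapped().swapped().pairs == aln.pairs


class TestRelDiff:
    def test_examples(self):
        assert rel_diff(1.3, 1.3) == 0.0
        assert rel_diff(1.0, 3.0) == pytest.approx(1.0, abs=1e-15)
        assert rel_diff(0.0, 0.0) == 0.0
        with pytest.raises(ValidationError):
            rel_diff(-0.1, 1.0)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(0, 50), st.floats(0, 50))
    def test_symmetric_and_bounded(self, a, b):
        d = rel_diff(a, b)
        assert d == rel_diff(b, a)
        assert 0.0 <= d <= 2.0
        assert rel_diff(a, b, norm="max") <= 1.0


class TestPms:
    def test_zero_crossing_at_cutoff(self):
        # symmetric s+/s- make the logistic midpoint x0 coincide with t
        assert DEFAULTS.x0 == DEFAULTS.t
        mid = DEFAULTS.t
        s_at_t = DEFAULTS.s_minus + (DEFAULTS.s_plus - DEFAULTS.s_minus) / (
            1 + math.exp(DEFAULTS.lam * (mid - DEFAULTS.x0))
        )
        assert s_at_t == pytest.approx(0.0, abs=1e-12)
        # asymmetric scores: zero crossing still lands exactly at t
        p = ScoreParams(s_plus=2.0, s_minus=-0.5, t=0.3, lam=25.0)
        from dfmalign.scoring import pms_of_d

        assert pms_of_d(p.t, p) == pytest.approx(0.0, abs=1e-12)

    def test_identical_entries_score_near_ceiling(self):
        assert pms(1.3, 1.3) > 0.99

    def test_maximal_difference_scores_near_floor(self):
        s = pms(2.0, 0.0)  # d = 2, the mean-normalised maximum
        assert abs(s - DEFAULTS.s_minus) < 1e-3

    def test_monotone_decreasing_and_bounded(self):
        from dfmalign.scoring import pms_of_d

        grid = np.linspace(0, 2, 201)
        vals = pms_of_d(grid, DEFAULTS)
        # non-increasing everywhere; strictly decreasing where not saturated
        assert np.all(np.diff(vals) <= 0)
        mid = (grid > DEFAULTS.t - 0.1) & (grid < DEFAULTS.t + 0.1)
        assert np.all(np.diff(vals[mid]) < 0)
        assert np.all(vals >= DEFAULTS.s_minus) and np.all(vals <= DEFAULTS.s_plus)
        assert np.all((vals > 0) == (grid < DEFAULTS.t))


class TestSubmatrices:
    def test_identity_alignment_is_identity(self, random_dfm):
        dfm = random_dfm(5)
        sub_a, sub_b = extract_submatrices(dfm, dfm, Alignment.identity(5))
        assert np.array_equal(sub_a, dfm.matrix)
        assert np.array_equal(sub_b, dfm.matrix)

    def test_definitional_indexing(self, random_dfm):
        fa, fb = random_dfm(4), random_dfm(4)
        aln = Alignment([(0, 1), (2, 3)])
        sub_a, sub_b = extract_submatrices(fa, fb, aln)
        assert sub_a[0, 1] == fa.matrix[0, 2]
        assert sub_b[0, 1] == fb.matrix[1, 3]

    def test_empty_alignment(self, random_dfm):
        sub_a, sub_b = extract_submatrices(random_dfm(3), random_dfm(3), Alignment([]))
        assert sub_a.shape == (0, 0) and sub_b.shape == (0, 0)

    def test_out_of_range_rejected(self, random_dfm):
        with pytest.raises(ValidationError):
            extract_submatrices(random_dfm(3), random_dfm(3), Alignment([(0, 5)]))


def random_instance(rng, random_dfm, na=None, nb=None):
    na = na or int(rng.integers(3, 8))
    nb = nb or int(rng.integers(3, 8))
    fa, fb = random_dfm(na), random_dfm(nb)
    k = int(rng.integers(0, min(na, nb) + 1))
    a = np.sort(rng.choice(na, k, replace=False))
    b = np.sort(rng.choice(nb, k, replace=False))
    return fa, fb, Alignment(list(zip(a.tolist(), b.tolist())))


class TestAlignmentScore:
    def test_self_alignment_is_maximal(self, random_dfm):
        dfm = random_dfm(6)
        aln = Alignment.identity(6)
        expected = math.comb(6, 2) * pms(1.0, 1.0)
        assert alignment_score(dfm, dfm, aln) == pytest.approx(expected, rel=1e-12)

    def test_short_alignments_score_zero(self, random_dfm):
        fa, fb = random_dfm(4), random_dfm(4)
        assert alignment_score(fa, fb, Alignment([])) == 0.0
        assert alignment_score(fa, fb, Alignment([(1, 2)])) == 0.0

    def test_matches_brute_force(self, rng, random_dfm):
        for _ in range(30):
            fa, fb, aln = random_instance(rng, random_dfm)
            got = alignment_score(fa, fb, aln)
            assert got == pytest.approx(brute_force_score(fa, fb, aln.pairs), abs=1e-10)

    def test_symmetry_under_swap(self, rng, random_dfm):
        for _ in range(10):
            fa, fb, aln = random_instance(rng, random_dfm)
            assert alignment_score(fa, fb, aln) == alignment_score(fb, fa, aln.swapped())


class TestSms:
    def test_identity_self_alignment_sms(self, random_dfm):
        dfm = random_dfm(5)
        sms = sms_profile(dfm, dfm, Alignment.identity(5))
        assert np.allclose(sms, 4 * pms(1.0, 1.0))
        assert np.all(sms > 0)

    def test_removal_identity_every_column(self, rng, random_dfm):
        for _ in range(15):
            fa, fb, aln = random_instance(rng, random_dfm)
            if aln.n_cols == 0:
                continue
            total = alignment_score(fa, fb, aln)
            sms = sms_profile(fa, fb, aln)
            for i in range(aln.n_cols):
                drop = total - alignment_score(fa, fb, aln.without_column(i))
                assert drop == pytest.approx(sms[i], abs=1e-9)

    def test_half_sum_identity(self, rng, random_dfm):
        for _ in range(15):
            fa, fb, aln = random_instance(rng, random_dfm)
            total = alignment_score(fa, fb, aln)
            assert total == pytest.approx(0.5 * sms_profile(fa, fb, aln).sum(),
                                          rel=1e-9, abs=1e-12)

    def test_two_column_alignment(self, random_dfm):
        fa, fb = random_dfm(4), random_dfm(4)
        aln = Alignment([(0, 1), (2, 3)])
        sms = sms_profile(fa, fb, aln)
        total = alignment_score(fa, fb, aln)
        assert sms[0] == pytest.approx(total) and sms[1] == pytest.approx(total)


def test_score_alignment_bundles_consistent_parts(rng, random_dfm):
    fa, fb, aln = random_instance(rng, random_dfm, na=6, nb=7)
    scored = score_alignment(fa, fb, aln)
    assert scored.total_score == pytest.approx(alignment_score(fa, fb, aln))
    assert scored.collapsed_a.shape == (aln.n_cols, aln.n_cols)
    assert scored.total_score == pytest.approx(0.5 * scored.sms.sum(), abs=1e-12)
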