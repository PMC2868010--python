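"""Simulated-annealing matrix alignment: moves, schedule, oracle agreement."""

import math

import numpy as np
import pytest

from dfmalign.align import (
    SAConfig,
    anneal,
    calibrate_t0,
    exhaustive_optimum,
    feasible_insertions,
    propose_move,
    prune_negative_sms,
    random_alignment,
)
from dfmalign.dfm import DFM
from dfmalign.errors import SizeError, ValidationError
from dfmalign.scoring import Alignment, ScoreParams, alignment_score, pms, sms_profile

DEFAULTS = ScoreParams()


class TestSAConfig:
    def test_rejects_invalid_schedules(self):
        with pytest.raises(ValidationError):
            SAConfig(chi0=1.5)
        with pytest.raises(ValidationError):
            SAConfig(cooling_factor=1.0)
        with pytest.raises(ValidationError):
            SAConfig(stop_acceptance=0.9, chi0=0.8)
        with pytest.raises(ValidationError):
            SAConfig(n_restarts=0)


class TestProposeMove:
    def test_empty_alignment_gets_an_insertion(self, rng):
        nxt = propose_move(Alignment([]), 3, 3, rng)
        assert nxt.n_cols == 1

    def test_full_alignment_gets_a_removal(self, rng):
        full = Alignment.identity(3)
        nxt = propose_move(full, 3, 3, rng)
        assert nxt.n_cols == 2

    def test_neighbours_differ_by_one_column_and_stay_monotone(self, rng):
        aln = Alignment([(0, 1), (2, 3), (5, 4)])
        for _ in range(50):
            nxt = propose_move(aln, 7, 6, rng)
            assert abs(nxt.n_cols - aln.n_cols) == 1
            # Alignment construction re-validates monotonicity

    def test_feasible_insertions_enumeration(self):
        # brute-force over all cells: only (1,1) fits between (0,0) and (2,2)
        aln = Alignment([(0, 0), (2, 2)])
        assert feasible_insertions(aln, 3, 3) == [(1, 1)]

        brute = [
            (x, y)
            for x in range(3)
            for y in range(3)
            if _insertion_ok(aln.pairs, x, y)
        ]
        assert brute == [(1, 1)]


def _insertion_ok(pairs, x, y):
    if any(a == x or b == y for a, b in pairs):
        return False
    try:
        Alignment(sorted(pairs + [(x, y)]))
        return True
    except ValidationError:
        return False


class TestCalibrateT0:
    def test_chi0_scaling_is_exact(self, random_dfm, rng):
        fa, fb = random_dfm(8), random_dfm(8)
        t_a = calibrate_t0(fa, fb, DEFAULTS, SAConfig(chi0=1 / math.e, seed=3),
                           np.random.default_rng(3))
        t_b = calibrate_t0(fa, fb, DEFAULTS, SAConfig(chi0=0.8, seed=3),
                           np.random.default_rng(3))
        # same pilot walk, so T0 ratio equals the ratio of 1/ln(1/chi0)
        assert t_b / t_a == pytest.approx(1.0 / math.log(1.25), rel=1e-12)

    def test_johnson_formula_arithmetic(self):
        # mean downhill magnitude 2.0 at chi0 = 0.8 gives T0 = 2/ln(1.25)
        assert 2.0 / math.log(1.0 / 0.8) == pytest.approx(8.9628, abs=5e-4)

    def test_no_downhill_fallback(self):
        # single-residue DFMs: every alignment scores 0, pilot sees no descent
        one = DFM(np.zeros((1, 1)))
        t0 = calibrate_t0(one, one, DEFAULTS, SAConfig(), np.random.default_rng(0))
        assert t0 == 1.0


class TestExhaustive:
    def test_single_residue_instance(self):
        one = DFM(np.zeros((1, 1)))
        best = exhaustive_optimum(one, one)
        assert best.n_cols <= 1 and best.total_score == 0.0

    def test_identical_dfms_give_identity(self, random_dfm):
        dfm = random_dfm(4)
        best = exhaustive_optimum(dfm, dfm)
        assert best.alignment.pairs == Alignment.identity(4).pairs
        assert best.total_score == pytest.approx(6 * pms(1.0, 1.0), rel=1e-12)

    def test_enumeration_count_vandermonde(self):
        # independent counter over all monotone matchings of two 4-chains
        def count(a_next, b_next, na, nb):
            total = 1  # the current (possibly empty) alignment
            for x in range(a_next, na):
                for y in range(b_next, nb):
                    total += count(x + 1, y + 1, na, nb)
            return total

        assert count(0, 0, 4, 4) == math.comb(8, 4) == 70

    def test_size_guard(self, random_dfm):
        with pytest.raises(SizeError):
            exhaustive_optimum(random_dfm(30), random_dfm(30))


class TestAnneal:
    def test_reproducible_under_fixed_seed(self, random_dfm):
        fa, fb = random_dfm(12), random_dfm(12)
        cfg = SAConfig(seed=42, n_restarts=3)
        r1 = anneal(fa, fb, DEFAULTS, cfg)
        r2 = anneal(fa, fb, DEFAULTS, cfg)
        assert r1.best.alignment.pairs == r2.best.alignment.pairs
        assert r1.best.total_score == r2.best.total_score
        assert r1.per_restart_scores == r2.per_restart_scores

    def test_best_is_max_of_restarts(self, random_dfm):
        fa, fb = random_dfm(10), random_dfm(11)
        res = anneal(fa, fb, DEFAULTS, SAConfig(seed=5, n_restarts=4))
        assert res.best.total_score == max(res.per_restart_scores)

    def test_matches_exhaustive_on_small_instances(self, rng, random_dfm):
        hits = 0
        for k in range(15):
            na, nb = int(rng.integers(3, 7)), int(rng.integers(3, 7))
            fa, fb = random_dfm(na), random_dfm(nb)
            opt = exhaustive_optimum(fa, fb)
            res = anneal(fa, fb, DEFAULTS, SAConfig(seed=k, n_restarts=5))
            assert res.best.total_score <= opt.total_score + 1e-9
            hits += abs(res.best.total_score - opt.total_score) < 1e-9
        assert hits >= 14

    def test_quasi_greedy_run_ends_in_local_optimum(self, random_dfm):
        fa, fb = random_dfm(6), random_dfm(6)
        cfg = SAConfig(seed=8, n_restarts=1, t0=1e-9, prune_negative_sms=False)
        res = anneal(fa, fb, DEFAULTS, cfg)
        best = res.best
        score = best.total_score
        # no single insertion or removal improves the returned alignment
        for x, y in feasible_insertions(best.alignment, 6, 6):
            grown = Alignment(sorted(best.alignment.pairs + [(x, y)]))
            assert alignment_score(fa, fb, grown) <= score + 1e-9
        for i in range(best.n_cols):
            shrunk = best.alignment.without_column(i)
            assert alignment_score(fa, fb, shrunk) <= score + 1e-9

    def test_annealing_beats_or_ties_greedy(self, rng, random_dfm):
        wins = ties = 0
        for k in range(10):
            fa, fb = random_dfm(8), random_dfm(8)
            greedy = anneal(fa, fb, DEFAULTS, SAConfig(seed=k, n_restarts=2, t0=1e-9))
            annealed = anneal(fa, fb, DEFAULTS, SAConfig(seed=k, n_restarts=2))
            assert annealed.best.total_score >= greedy.best.total_score - 1e-9
            wins += annealed.best.total_score > greedy.best.total_score + 1e-9
            ties += abs(annealed.best.total_score - greedy.best.total_score) <= 1e-9
        assert wins + ties == 10

    def test_trace_is_recorded_when_requested(self, random_dfm):
        fa, fb = random_dfm(6), random_dfm(6)
        res = anneal(fa, fb, DEFAULTS,
                     SAConfig(seed=1, n_restarts=2, record_trace=True))
        assert res.trace
        restarts, temps, _, ratios = zip(*res.trace)
        assert set(restarts) == {0, 1}
        assert all(r <= 1.0 for r in ratios)


class TestPruning:
    def test_pruned_alignment_has_nonnegative_sms(self, rng, random_dfm):
        for k in range(10):
            fa, fb = random_dfm(9), random_dfm(9)
            res = anneal(fa, fb, DEFAULTS, SAConfig(seed=k, n_restarts=2))
            if res.best.n_cols >= 2:
                assert res.best.sms.min() >= 0.0

    def test_pruning_never_lowers_the_score(self, rng, random_dfm):
        for _ in range(10):
            fa, fb = random_dfm(8), random_dfm(8)
            aln = random_alignment(8, 8, rng, k=6)
            before = alignment_score(fa, fb, aln)
            pruned = prune_negative_sms(fa, fb, aln, DEFAULTS)
            after = alignment_score(fa, fb, pruned)
            assert after >= before - 1e-12
            if pruned.n_cols >= 2:
                assert sms_profile(fa, fb, pruned, DEFAULTS).min() >= 0.0
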