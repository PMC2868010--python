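"""Dynamics-based alignment of two DFMs by multiple-restart simulated annealing.

Finding the monotone residue correspondence that maximises the dynamic
similarity score is NP-hard (it is a matrix-alignment problem, as in Dali or
MatAlign), so the optimum is approximated by a Markov-chain Monte Carlo
search: starting from a random alignment, single match columns are inserted
or removed and accepted by the Metropolis criterion at a temperature that
decays exponentially.  The chain must log a minimum number of accepted moves
per temperature plateau; the initial temperature is calibrated from a pilot
random walk (Johnson's method) to hit a target initial acceptance ratio, and
a run terminates once the per-plateau acceptance ratio drops below a
threshold.  The whole procedure is restarted from independent random states
and the best alignment ever visited is returned.  Optimal alignments contain
only columns of non-negative Single Match Score, so negative-SMS columns can
be pruned from the result (each removal raises the total score).

The hot loop is JIT-compiled (numba); an exhaustive enumerator over all
monotone alignments provides the exact optimum on small instances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .dfm import DFM
from .errors import SizeError, ValidationError
from .scoring import (
    Alignment,
    ScoredAlignment,
    ScoreParams,
    alignment_score,
    score_alignment,
    sms_profile,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SAConfig",
    "AlignResult",
    "propose_move",
    "random_alignment",
    "calibrate_t0",
    "anneal",
    "exhaustive_optimum",
    "prune_negative_sms",
]


@dataclass(frozen=True)
class SAConfig:
    """Simulated-annealing schedule and restart policy.

    chi0
        Target initial acceptance ratio of score-decreasing moves; used to
        calibrate the initial temperature from a pilot walk.
    plateau_min_accepts
        Accepted moves required before the temperature is reduced; ``None``
        scales it as 50·min(n_a, n_b).
    cooling_factor
        Multiplicative temperature decay per plateau (exponential schedule).
    stop_acceptance
        A run terminates when the acceptance ratio over a plateau falls
        below this value.
    n_restarts
        Independent runs from random initial alignments; the best alignment
        visited by any run is returned.
    seed
        Master RNG seed; fixed seed gives bitwise-identical results.
    prune_negative_sms
        Iteratively remove negative-SMS columns from each run's best
        alignment (most negative first), which can only raise the score.
    t0
        Optional initial-temperature override (skips pilot calibration);
        useful for forcing quasi-greedy behaviour.
    pilot_steps
        Length of the calibration random walk; ``None`` scales with size.
    """

    chi0: float = 0.8
    plateau_min_accepts: int | None = None
    cooling_factor: float = 0.95
    stop_acceptance: float = 0.02
    n_restarts: int = 5
    seed: int = 0
    prune_negative_sms: bool = True
    t0: float | None = None
    pilot_steps: int | None = None
    record_trace: bool = False
    max_plateaus: int = 100_000

    def __post_init__(self) -> None:
        if not 0.0 < self.chi0 < 1.0:
            raise ValidationError("chi0 must be in (0, 1)")
        if not 0.0 < self.cooling_factor < 1.0:
            raise ValidationError("cooling_factor must be in (0, 1)")
        if not 0.0 <= self.stop_acceptance < self.chi0:
            raise ValidationError("need 0 <= stop_acceptance < chi0")
        if self.plateau_min_accepts is not None and self.plateau_min_accepts < 1:
            raise ValidationError("plateau_min_accepts must be >= 1")
        if self.n_restarts < 1:
            raise ValidationError("n_restarts must be >= 1")
        if self.t0 is not None and self.t0 <= 0:
            raise ValidationError("t0 override must be positive")

    def resolved_plateau(self, na: int, nb: int) -> int:
        if self.plateau_min_accepts is not None:
            return self.plateau_min_accepts
        return 50 * min(na, nb)


@dataclass
class AlignResult:
    """Outcome of a multiple-restart annealing run.

    ``best.total_score`` equals the maximum of ``per_restart_scores``; with
    pruning enabled every SMS of the best alignment is non-negative.
    """

    best: ScoredAlignment
    per_restart_scores: list[float]
    trace: list[tuple[int, float, float, float]] | None = None


# ---------------------------------------------------------------------------
# moves (reference implementation; the JIT kernel mirrors this logic)
# ---------------------------------------------------------------------------

def feasible_insertions(aln: Alignment, na: int, nb: int) -> list[tuple[int, int]]:
    """All single-column insertions preserving strict monotonicity."""
    cols = aln.pairs
    k = len(cols)
    out: list[tuple[int, int]] = []
    for g in range(k + 1):
        a_lo = cols[g - 1][0] if g > 0 else -1
        a_hi = cols[g][0] if g < k else na
        b_lo = cols[g - 1][1] if g > 0 else -1
        b_hi = cols[g][1] if g < k else nb
        for x in range(a_lo + 1, a_hi):
            for y in range(b_lo + 1, b_hi):
                out.append((x, y))
    return out


def propose_move(
    aln: Alignment, na: int, nb: int, rng: np.random.Generator
) -> Alignment:
    """Return a neighbouring alignment differing by one match column.

    Insertions and removals are proposed with equal probability when both
    are feasible; an empty alignment only admits insertions and a full one
    only removals.
    """
    if na < 1 or nb < 1:
        raise ValidationError("cannot propose a move between empty proteins")
    k = aln.n_cols
    insertions = feasible_insertions(aln, na, nb)
    can_insert = bool(insertions)
    can_remove = k > 0
    if not can_insert and not can_remove:
        raise ValidationError("no feasible move")
    if can_insert and (not can_remove or rng.random() < 0.5):
        x, y = insertions[int(rng.integers(len(insertions)))]
        pairs = sorted(aln.pairs + [(x, y)])
        return Alignment(pairs)
    i = int(rng.integers(k))
    return aln.without_column(i)


def random_alignment(na: int, nb: int, rng: np.random.Generator,
                     k: int | None = None) -> Alignment:
    """A uniform random monotone k-matching (k ~ U[0, min(na, nb)/2] if unset)."""
    kmax = min(na, nb)
    if k is None:
        k = int(rng.integers(0, max(kmax // 2, 1) + 1))
    if k > kmax:
        raise ValidationError(f"k={k} exceeds min(na, nb)={kmax}")
    if k == 0:
        return Alignment([])
    a = np.sort(rng.choice(na, size=k, replace=False))
    b = np.sort(rng.choice(nb, size=k, replace=False))
    return Alignment(list(zip(a.tolist(), b.tolist())))


# ---------------------------------------------------------------------------
# temperature calibration
# ---------------------------------------------------------------------------

def calibrate_t0(
    dfm_a: DFM,
    dfm_b: DFM,
    params: ScoreParams,
    cfg: SAConfig,
    rng: np.random.Generator,
) -> float:
    """Initial temperature from a pilot random walk (Johnson's method).

    Every proposed move is accepted; the mean magnitude Δ̄⁺ of
    score-decreasing moves gives T0 = Δ̄⁺ / ln(1/chi0), so that downhill
    moves start out accepted with probability ≈ chi0.
    """
    na, nb = dfm_a.n_residues, dfm_b.n_residues
    steps = cfg.pilot_steps or max(200, 10 * min(na, nb))
    aln = random_alignment(na, nb, rng)
    score = alignment_score(dfm_a, dfm_b, aln, params)
    downhill: list[float] = []
    for _ in range(steps):
        nxt = propose_move(aln, na, nb, rng)
        nxt_score = alignment_score(dfm_a, dfm_b, nxt, params)
        delta = nxt_score - score
        if delta < 0:
            downhill.append(-delta)
        aln, score = nxt, nxt_score
    if not downhill:
        logger.warning(
            "pilot walk saw no score-decreasing moves; falling back to T0 = 1.0"
        )
        return 1.0
    return float(np.mean(downhill)) / math.log(1.0 / cfg.chi0)


# ---------------------------------------------------------------------------
# JIT-compiled annealing chain
# ---------------------------------------------------------------------------

@njit(cache=False, fastmath=False)
def _pms_scalar(x, y, s_plus, s_minus, lam, x0, mean_norm):
    if mean_norm:
        denom = 0.5 * (x + y)
    else:
        denom = x if x > y else y
    if denom > 0.0:
        d = abs(x - y) / denom
    else:
        d = 0.0
    z = lam * (d - x0)
    if z > 700.0:
        z = 700.0
    elif z < -700.0:
        z = -700.0
    return s_minus + (s_plus - s_minus) / (1.0 + math.exp(z))


@njit(cache=False)
def _sa_chain(
    fa, fb, s_plus, s_minus, lam, x0, mean_norm,
    t0, cooling, plateau_accepts, stop_ratio, max_plateaus,
    seed, init_a, init_b, trace_t, trace_s, trace_r,
):
    np.random.seed(seed)
    na = fa.shape[0]
    nb = fb.shape[0]
    kmax = min(na, nb)
    a = np.empty(kmax, np.int64)
    b = np.empty(kmax, np.int64)
    k = init_a.size
    a[:k] = init_a
    b[:k] = init_b

    # full score of the initial state
    cur = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            cur += _pms_scalar(fa[a[i], a[j]], fb[b[i], b[j]],
                               s_plus, s_minus, lam, x0, mean_norm)

    best_a = a[:k].copy()
    best_b = b[:k].copy()
    best_k = k
    best = cur

    max_prop = int(plateau_accepts / stop_ratio) + 1 if stop_ratio > 0 else 200 * plateau_accepts
    T = t0
    n_plateaus = 0
    while n_plateaus < max_plateaus:
        accepts = 0
        proposals = 0
        while accepts < plateau_accepts and proposals < max_prop:
            proposals += 1
            do_insert = False
            if k == 0:
                do_insert = True
            elif k < kmax:
                do_insert = np.random.random() < 0.5
            if do_insert:
                # sample a feasible insertion by rejection on residue x of A
                found = False
                x = -1
                y = -1
                g = 0
                for _attempt in range(8):
                    x = np.random.randint(0, na)
                    g = 0
                    while g < k and a[g] < x:
                        g += 1
                    if g < k and a[g] == x:
                        continue
                    lo = b[g - 1] if g > 0 else -1
                    hi = b[g] if g < k else nb
                    if hi - lo <= 1:
                        continue
                    y = lo + 1 + np.random.randint(0, hi - lo - 1)
                    found = True
                    break
                if not found:
                    continue
                delta = 0.0
                for j in range(k):
                    delta += _pms_scalar(fa[x, a[j]], fb[y, b[j]],
                                         s_plus, s_minus, lam, x0, mean_norm)
                if delta >= 0.0 or np.random.random() < math.exp(delta / T):
                    for j in range(k, g, -1):
                        a[j] = a[j - 1]
                        b[j] = b[j - 1]
                    a[g] = x
                    b[g] = y
                    k += 1
                    cur += delta
                    accepts += 1
                    if cur > best:
                        best = cur
                        best_k = k
                        best_a = a[:k].copy()
                        best_b = b[:k].copy()
            else:
                i = np.random.randint(0, k)
                delta = 0.0
                for j in range(k):
                    if j != i:
                        delta -= _pms_scalar(fa[a[i], a[j]], fb[b[i], b[j]],
                                             s_plus, s_minus, lam, x0, mean_norm)
                if delta >= 0.0 or np.random.random() < math.exp(delta / T):
                    for j in range(i, k - 1):
                        a[j] = a[j + 1]
                        b[j] = b[j + 1]
                    k -= 1
                    cur += delta
                    accepts += 1
                    if cur > best:
                        best = cur
                        best_k = k
                        best_a = a[:k].copy()
                        best_b = b[:k].copy()
        ratio = accepts / proposals if proposals > 0 else 0.0
        if n_plateaus < trace_t.size:
            trace_t[n_plateaus] = T
            trace_s[n_plateaus] = cur
            trace_r[n_plateaus] = ratio
        n_plateaus += 1
        if ratio < stop_ratio:
            break
        T *= cooling
    return best_a[:best_k], best_b[:best_k], best, n_plateaus


# ---------------------------------------------------------------------------
# pruning and the public driver
# ---------------------------------------------------------------------------

def prune_negative_sms(
    dfm_a: DFM, dfm_b: DFM, aln: Alignment, params: ScoreParams
) -> Alignment:
    """Iteratively remove the most negative-SMS column until none remain.

    Each removal raises the total score by −SMS > 0, so pruning never
    lowers the score; the result has min(SMS) ≥ 0 (or fewer than 2 columns).
    """
    while aln.n_cols >= 2:
        sms = sms_profile(dfm_a, dfm_b, aln, params)
        worst = int(np.argmin(sms))
        if sms[worst] >= 0.0:
            break
        aln = aln.without_column(worst)
    return aln


def anneal(
    dfm_a: DFM,
    dfm_b: DFM,
    params: ScoreParams = ScoreParams(),
    cfg: SAConfig = SAConfig(),
) -> AlignResult:
    """Approximately maximise the dynamic similarity score of two DFMs.

    Runs ``cfg.n_restarts`` independent annealing chains from random initial
    alignments and returns the best-ever alignment across restarts (after
    optional negative-SMS pruning of each restart's best).  Deterministic
    for a fixed ``cfg.seed``.
    """
    na, nb = dfm_a.n_residues, dfm_b.n_residues
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0xA11]))
    t0 = cfg.t0 if cfg.t0 is not None else calibrate_t0(dfm_a, dfm_b, params, cfg, rng)
    plateau = cfg.resolved_plateau(na, nb)
    mean_norm = params.rel_diff_norm == "mean"

    trace_cap = min(cfg.max_plateaus, 20_000)
    best_scored: ScoredAlignment | None = None
    per_restart: list[float] = []
    trace: list[tuple[int, float, float, float]] | None = (
        [] if cfg.record_trace else None
    )
    fa = np.ascontiguousarray(dfm_a.matrix)
    fb = np.ascontiguousarray(dfm_b.matrix)
    for r in range(cfg.n_restarts):
        init = random_alignment(na, nb, rng)
        kernel_seed = int(rng.integers(0, 2**31 - 1))
        tt = np.zeros(trace_cap)
        ts = np.zeros(trace_cap)
        tr = np.zeros(trace_cap)
        ba, bb, kernel_score, n_plat = _sa_chain(
            fa, fb,
            params.s_plus, params.s_minus, params.lam, params.x0, mean_norm,
            t0, cfg.cooling_factor, plateau, cfg.stop_acceptance,
            cfg.max_plateaus, kernel_seed,
            init.alpha(), init.beta(), tt, ts, tr,
        )
        aln = Alignment(list(zip(ba.tolist(), bb.tolist())))
        rescored = alignment_score(dfm_a, dfm_b, aln, params)
        # incremental bookkeeping in the chain must agree with a full rescore
        if abs(rescored - kernel_score) > 1e-6 * max(1.0, abs(rescored)):
            raise RuntimeError(
                f"incremental score {kernel_score} disagrees with rescore {rescored}"
            )
        if cfg.prune_negative_sms:
            aln = prune_negative_sms(dfm_a, dfm_b, aln, params)
        scored = score_alignment(dfm_a, dfm_b, aln, params)
        per_restart.append(scored.total_score)
        if trace is not None:
            for p in range(min(n_plat, trace_cap)):
                trace.append((r, float(tt[p]), float(ts[p]), float(tr[p])))
        if best_scored is None or scored.total_score > best_scored.total_score:
            best_scored = scored
    assert best_scored is not None
    return AlignResult(best=best_scored, per_restart_scores=per_restart, trace=trace)


# ---------------------------------------------------------------------------
# exact optimum on small instances
# ---------------------------------------------------------------------------

def exhaustive_optimum(
    dfm_a: DFM,
    dfm_b: DFM,
    params: ScoreParams = ScoreParams(),
    max_alignments: int = 10**6,
) -> ScoredAlignment:
    """Exact maximum-score alignment by enumerating every monotone matching.

    The number of monotone alignments of chains of lengths n_a, n_b is
    C(n_a + n_b, n_a) (Vandermonde); instances beyond ``max_alignments``
    are refused.  Ties are broken toward more columns, then the
    lexicographically smallest pair list.
    """
    na, nb = dfm_a.n_residues, dfm_b.n_residues
    total = math.comb(na + nb, na)
    if total > max_alignments:
        raise SizeError(
            f"{total} monotone alignments exceed the exhaustive limit "
            f"{max_alignments}; use anneal() instead"
        )
    fa, fb = dfm_a.matrix, dfm_b.matrix
    sp, sm, lam, x0 = params.s_plus, params.s_minus, params.lam, params.x0
    mean_norm = params.rel_diff_norm == "mean"

    def col_pms(x, y, cols):
        s = 0.0
        for (ax, bx) in cols:
            u, v = fa[x, ax], fb[y, bx]
            denom = 0.5 * (u + v) if mean_norm else max(u, v)
            d = abs(u - v) / denom if denom > 0 else 0.0
            z = min(max(lam * (d - x0), -700.0), 700.0)
            s += sm + (sp - sm) / (1.0 + math.exp(z))
        return s

    best_pairs: list[tuple[int, int]] = []
    best_score = 0.0

    def consider(cols: list[tuple[int, int]], score: float) -> None:
        nonlocal best_pairs, best_score
        if (score > best_score
                or (score == best_score
                    and (len(cols) > len(best_pairs)
                         or (len(cols) == len(best_pairs) and cols < best_pairs)))):
            best_score = score
            best_pairs = list(cols)

    def recurse(a_next: int, b_next: int, cols: list[tuple[int, int]], score: float) -> None:
        consider(cols, score)
        for x in range(a_next, na):
            for y in range(b_next, nb):
                add = col_pms(x, y, cols)
                cols.append((x, y))
                recurse(x + 1, y + 1, cols, score + add)
                cols.pop()

    recurse(0, 0, [], 0.0)
    return score_alignment(dfm_a, dfm_b, Alignment(best_pairs), params)
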