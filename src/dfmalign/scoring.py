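"""Dynamic similarity scoring of two DFMs under a residue alignment.

A gap-free column k of a pairwise alignment matches residue α(k) of protein A
with residue β(k) of protein B.  Restricting each DFM to the aligned residues
yields two |α|×|α| "collapsed" submatrices whose (i, j) entries describe the
fluctuation of *equivalent* residue pairs.  Each equivalent entry pair is
compared through an S-shaped logistic score (the Pairwise Match Score, PMS)
of their relative difference d: near-identical fluctuations earn up to s₊,
strongly dissimilar ones as little as s₋, and the score crosses zero exactly
at the cut-off d = t.  The total alignment score is the sum of PMS over all
unordered column pairs; the Single Match Score (SMS) of a column is its total
PMS against all other columns, i.e. exactly the score lost by deleting it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log

import numpy as np

from .dfm import DFM
from .errors import ValidationError

__all__ = [
    "Alignment",
    "ScoreParams",
    "ScoredAlignment",
    "extract_submatrices",
    "rel_diff",
    "pms",
    "alignment_score",
    "sms_profile",
    "score_alignment",
]


@dataclass
class Alignment:
    """An ordered, strictly monotone set of match columns (α(k), β(k)).

    ``pairs`` is a sequence of (a_k, b_k) 0-based residue indices; both index
    vectors must be strictly increasing, as for the match columns of a gapped
    pairwise alignment.
    """

    pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pairs = [(int(a), int(b)) for a, b in self.pairs]
        a_prev, b_prev = -1, -1
        for k, (a, b) in enumerate(self.pairs):
            if a < 0 or b < 0:
                raise ValidationError(f"negative residue index in column {k}")
            if a <= a_prev or b <= b_prev:
                raise ValidationError(
                    f"alignment index vectors must be strictly increasing "
                    f"(violated at column {k})"
                )
            a_prev, b_prev = a, b

    @property
    def n_cols(self) -> int:
        return len(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def alpha(self) -> np.ndarray:
        """Index vector into protein A."""
        return np.array([a for a, _ in self.pairs], dtype=np.intp)

    def beta(self) -> np.ndarray:
        """Index vector into protein B."""
        return np.array([b for _, b in self.pairs], dtype=np.intp)

    def swapped(self) -> "Alignment":
        """The same alignment read as B-vs-A."""
        return Alignment([(b, a) for a, b in self.pairs])

    def without_column(self, i: int) -> "Alignment":
        if not 0 <= i < len(self.pairs):
            raise ValidationError(f"column {i} out of range")
        return Alignment(self.pairs[:i] + self.pairs[i + 1:])

    def validate_for(self, dfm_a: DFM, dfm_b: DFM) -> None:
        if self.pairs:
            a_max = max(a for a, _ in self.pairs)
            b_max = max(b for _, b in self.pairs)
            if a_max >= dfm_a.n_residues or b_max >= dfm_b.n_residues:
                raise ValidationError(
                    "alignment indexes residues beyond the DFM sizes "
                    f"({a_max} vs {dfm_a.n_residues}, {b_max} vs {dfm_b.n_residues})"
                )

    @staticmethod
    def identity(n: int) -> "Alignment":
        return Alignment([(i, i) for i in range(n)])


@dataclass(frozen=True)
class ScoreParams:
    """Parameters of the logistic Pairwise Match Score.

    s_plus / s_minus
        Score ceiling for identical entries and floor for maximally
        dissimilar ones (dimensionless); must bracket zero.
    t
        Relative-difference cut-off: the PMS is positive exactly for d < t.
    lam
        Logistic steepness; large λ·t makes the score of identical entries
        approach s_plus and sharpens the switch at t.
    rel_diff_norm
        Normaliser of the relative difference: ``"mean"`` gives
        d = |a−b| / ((a+b)/2) (bounded in [0, 2]); ``"max"`` gives
        d = |a−b| / max(a, b) (bounded in [0, 1]).
    """

    s_plus: float = 1.0
    s_minus: float = -1.0
    t: float = 0.25
    lam: float = 40.0
    rel_diff_norm: str = "mean"

    def __post_init__(self) -> None:
        if not (self.s_plus > 0.0 > self.s_minus):
            raise ValidationError("need s_plus > 0 > s_minus")
        if self.t <= 0.0:
            raise ValidationError("cut-off t must be positive")
        if self.lam <= 0.0:
            raise ValidationError("steepness lam must be positive")
        if self.rel_diff_norm not in ("mean", "max"):
            raise ValidationError("rel_diff_norm must be 'mean' or 'max'")

    @property
    def x0(self) -> float:
        """Logistic midpoint shift solving s(t) = 0 in closed form."""
        return self.t - log(self.s_plus / (-self.s_minus)) / self.lam


def extract_submatrices(
    dfm_a: DFM, dfm_b: DFM, aln: Alignment
) -> tuple[np.ndarray, np.ndarray]:
    """Collapsed DFMs: the |α|×|α| principal submatrices of aligned residues."""
    aln.validate_for(dfm_a, dfm_b)
    alpha, beta = aln.alpha(), aln.beta()
    return (
        dfm_a.matrix[np.ix_(alpha, alpha)],
        dfm_b.matrix[np.ix_(beta, beta)],
    )


def rel_diff(a, b, norm: str = "mean"):
    """Relative difference of two equivalent fluctuation values.

    d = |a − b| / ((a + b) / 2) for the (default) mean normaliser, or
    |a − b| / max(a, b) for the max normaliser.  Both are symmetric,
    dimensionless, and defined as 0 when a = b = 0.  Accepts scalars or
    arrays (broadcasting).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a < 0.0) or np.any(b < 0.0):
        raise ValidationError("fluctuation values must be non-negative")
    if norm == "mean":
        denom = 0.5 * (a + b)
    elif norm == "max":
        denom = np.maximum(a, b)
    else:
        raise ValidationError("norm must be 'mean' or 'max'")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0.0, np.abs(a - b) / np.where(denom > 0, denom, 1.0), 0.0)
    return d if d.ndim else float(d)


def pms(a, b, params: ScoreParams = ScoreParams()):
    """Pairwise Match Score: logistic score of the relative difference.

    s(d) = s₋ + (s₊ − s₋) / (1 + exp(λ·(d − x₀))) with x₀ chosen so that
    s(t) = 0 exactly.  Strictly decreasing in d; positive iff d < t.
    Accepts scalars or arrays.
    """
    d = rel_diff(a, b, norm=params.rel_diff_norm)
    return pms_of_d(d, params)


def pms_of_d(d, params: ScoreParams = ScoreParams()):
    """PMS as a function of the relative difference d itself."""
    d = np.asarray(d, dtype=float)
    z = params.lam * (d - params.x0)
    # clip to keep exp() finite; the logistic saturates far before 700 anyway
    s = params.s_minus + (params.s_plus - params.s_minus) / (1.0 + np.exp(np.clip(z, -700, 700)))
    return s if s.ndim else float(s)


def _pms_matrix(dfm_a: DFM, dfm_b: DFM, aln: Alignment, params: ScoreParams) -> np.ndarray:
    """PMS of every column pair, as a symmetric k×k matrix with zero diagonal."""
    sub_a, sub_b = extract_submatrices(dfm_a, dfm_b, aln)
    k = sub_a.shape[0]
    if k < 2:
        return np.zeros((k, k))
    s = np.asarray(pms(sub_a, sub_b, params))
    np.fill_diagonal(s, 0.0)
    return s


def alignment_score(
    dfm_a: DFM, dfm_b: DFM, aln: Alignment, params: ScoreParams = ScoreParams()
) -> float:
    """Total dynamic similarity score of an alignment.

    Sum of PMS over unordered column pairs {i, j}, i < j.  Alignments with
    fewer than two columns score 0 (no pairs to compare).
    """
    s = _pms_matrix(dfm_a, dfm_b, aln, params)
    return float(s.sum() / 2.0)


def sms_profile(
    dfm_a: DFM, dfm_b: DFM, aln: Alignment, params: ScoreParams = ScoreParams()
) -> np.ndarray:
    """Single Match Scores: per-column sum of PMS against all other columns.

    SMS[i] equals exactly the drop in total alignment score caused by
    removing column i, making it a per-position confidence for the aligned
    residue pair.
    """
    s = _pms_matrix(dfm_a, dfm_b, aln, params)
    return s.sum(axis=1)


@dataclass
class ScoredAlignment:
    """An alignment together with its score decomposition.

    Invariant: ``total_score == 0.5 * sms.sum()`` — every pairwise score
    contributes to exactly two SMS entries.
    """

    alignment: Alignment
    total_score: float
    sms: np.ndarray
    collapsed_a: np.ndarray
    collapsed_b: np.ndarray

    @property
    def n_cols(self) -> int:
        return self.alignment.n_cols


def score_alignment(
    dfm_a: DFM, dfm_b: DFM, aln: Alignment, params: ScoreParams = ScoreParams()
) -> ScoredAlignment:
    """Score an alignment and assemble the full decomposition."""
    s = _pms_matrix(dfm_a, dfm_b, aln, params)
    sub_a, sub_b = extract_submatrices(dfm_a, dfm_b, aln)
    return ScoredAlignment(
        alignment=aln,
        total_score=float(s.sum() / 2.0),
        sms=s.sum(axis=1),
        collapsed_a=sub_a,
        collapsed_b=sub_b,
    )
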