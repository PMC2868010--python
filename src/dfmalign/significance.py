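"""Statistical significance of dynamic similarity scores.

The optimal alignment score of two unrelated proteins is the maximum over an
exponentially large set of alignment scores, so its null distribution is
well approximated by a type I extreme value (Gumbel) distribution.  The null
depends on the input sizes through L = L_A · L_B: the location μ(L) and
scale σ(L) are measured by aligning submatrices of unrelated reference DFMs
at several sizes, fitting a Gumbel per size bin, and regressing μ and σ on L
(or log L).  The p-value of an observed score S is the Gumbel upper tail

    p = 1 − exp(−exp(−(S − μ(L)) / σ(L))),

i.e. the chance that two unrelated proteins of these sizes reach a score of
at least S.  Scores with p < 0.05 are called significantly similar.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from math import exp, expm1, sqrt, pi

import numpy as np
from scipy import stats

from .align import SAConfig, anneal
from .dfm import DFM
from .errors import CalibrationError, DegenerateSampleError, ModelRangeError, ValidationError
from .scoring import ScoreParams

logger = logging.getLogger(__name__)

EULER_GAMMA = 0.5772156649015329

__all__ = [
    "EVDModel",
    "CalibrationPoint",
    "fit_gumbel",
    "calibrate",
    "pvalue",
    "is_significant",
    "synthetic_reference_dfms",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """Gumbel fit of the null-score distribution at one size L = L_A·L_B."""

    L: float
    mu: float
    sigma: float
    n_samples: int


@dataclass
class EVDModel:
    """Size-dependent Gumbel null model for optimal alignment scores.

    ``mu_coeffs`` and ``sigma_coeffs`` are (intercept, slope) of ordinary
    least-squares lines in the (optionally log-) transformed size
    x = transform(L):  μ(L) = a_μ + b_μ·x,  σ(L) = a_σ + b_σ·x.
    """

    mu_coeffs: tuple[float, float]
    sigma_coeffs: tuple[float, float]
    size_transform: str = "identity"
    calibration_points: list[CalibrationPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.size_transform not in ("identity", "log"):
            raise ValidationError("size_transform must be 'identity' or 'log'")
        if not self.calibration_points:
            raise ValidationError("calibration_points must be non-empty")
        if any(p.n_samples < 10 for p in self.calibration_points):
            raise ValidationError("every calibration point needs >= 10 samples")
        for p in self.calibration_points:
            if self.sigma(p.L) <= 0:
                raise ValidationError(
                    f"fitted sigma(L) is non-positive at calibrated L={p.L}"
                )

    def _x(self, L: float) -> float:
        if L < 1:
            raise ValidationError("L = La*Lb must be >= 1")
        return float(np.log(L)) if self.size_transform == "log" else float(L)

    def mu(self, L: float) -> float:
        a, b = self.mu_coeffs
        return a + b * self._x(L)

    def sigma(self, L: float) -> float:
        a, b = self.sigma_coeffs
        return a + b * self._x(L)

    @property
    def calibrated_range(self) -> tuple[float, float]:
        ls = [p.L for p in self.calibration_points]
        return min(ls), max(ls)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "mu_coeffs": list(self.mu_coeffs),
            "sigma_coeffs": list(self.sigma_coeffs),
            "size_transform": self.size_transform,
            "calibration_points": [
                {"L": p.L, "mu": p.mu, "sigma": p.sigma, "n_samples": p.n_samples}
                for p in self.calibration_points
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EVDModel":
        return cls(
            mu_coeffs=tuple(d["mu_coeffs"]),
            sigma_coeffs=tuple(d["sigma_coeffs"]),
            size_transform=d.get("size_transform", "identity"),
            calibration_points=[
                CalibrationPoint(p["L"], p["mu"], p["sigma"], p["n_samples"])
                for p in d["calibration_points"]
            ],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "EVDModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_gumbel(scores) -> tuple[float, float]:
    """Maximum-likelihood Gumbel(μ, σ) fit for maxima.

    Uses the method-of-moments values (σ₀ = sd·√6/π, μ₀ = mean − γ·σ₀) as
    the optimiser start.  Requires at least 10 finite scores and a
    non-degenerate sample.
    """
    scores = np.asarray(scores, dtype=float)
    scores = scores[np.isfinite(scores)]
    if scores.size < 10:
        raise ValidationError(f"need >= 10 finite scores, got {scores.size}")
    sd = float(scores.std(ddof=1))
    if sd == 0.0:
        raise DegenerateSampleError("all scores are equal; cannot fit a Gumbel")
    sigma0 = sd * sqrt(6.0) / pi
    mu0 = float(scores.mean()) - EULER_GAMMA * sigma0
    mu, sigma = stats.gumbel_r.fit(scores, loc=mu0, scale=sigma0)
    if sigma <= 0:  # pragma: no cover - scipy keeps scale positive
        raise DegenerateSampleError("Gumbel fit produced non-positive scale")
    return float(mu), float(sigma)


def calibrate(
    reference_dfms: list[DFM],
    params: ScoreParams,
    cfg: SAConfig,
    sub_sizes: list[int],
    rng: np.random.Generator,
    size_transform: str = "identity",
    repeats: int = 1,
    min_bin: int = 10,
) -> EVDModel:
    """Fit the size-dependent Gumbel null from unrelated reference DFMs.

    For every unordered pair of references and every requested submatrix
    size, a random contiguous principal submatrix of each DFM is aligned by
    ``anneal`` (contiguous blocks preserve the banded near-diagonal texture
    of real DFMs).  Scores are binned by L = L_A·L_B, a Gumbel is fitted per
    bin, and μ, σ are regressed on the (transformed) L by OLS.
    """
    if len(reference_dfms) < 4:
        raise ValidationError("calibration needs >= 4 reference DFMs")
    if not sub_sizes:
        raise ValidationError("sub_sizes must be non-empty")
    bins: dict[float, list[float]] = {}
    n_pairs = 0
    for i in range(len(reference_dfms)):
        for j in range(i + 1, len(reference_dfms)):
            n_pairs += 1
            for size in sub_sizes:
                for _ in range(repeats):
                    sub_a = _random_principal_submatrix(reference_dfms[i], size, rng)
                    sub_b = _random_principal_submatrix(reference_dfms[j], size, rng)
                    run_cfg = _with_seed(cfg, int(rng.integers(0, 2**31 - 1)))
                    result = anneal(sub_a, sub_b, params, run_cfg)
                    L = float(sub_a.n_residues * sub_b.n_residues)
                    bins.setdefault(L, []).append(result.best.total_score)
    logger.info("calibration: %d alignments over %d pairs, %d bins",
                sum(len(v) for v in bins.values()), n_pairs, len(bins))
    points: list[CalibrationPoint] = []
    for L in sorted(bins):
        scores = bins[L]
        if len(scores) < min_bin:
            raise CalibrationError(
                f"bin L={L:g} has only {len(scores)} scores (< {min_bin}); "
                "add references, sizes or repeats"
            )
        mu, sigma = fit_gumbel(scores)
        points.append(CalibrationPoint(L, mu, sigma, len(scores)))
    if len(points) < 2:
        raise CalibrationError("need >= 2 distinct L bins to regress mu(L), sigma(L)")
    xs = np.array([np.log(p.L) if size_transform == "log" else p.L for p in points])
    mus = np.array([p.mu for p in points])
    sigmas = np.array([p.sigma for p in points])
    b_mu, a_mu = np.polyfit(xs, mus, 1)
    b_sg, a_sg = np.polyfit(xs, sigmas, 1)
    if np.any(np.diff(mus) < 0):
        logger.warning(
            "fitted mu(L) is not monotone over the calibration points: %s",
            [(p.L, round(p.mu, 3)) for p in points],
        )
    return EVDModel(
        mu_coeffs=(float(a_mu), float(b_mu)),
        sigma_coeffs=(float(a_sg), float(b_sg)),
        size_transform=size_transform,
        calibration_points=points,
    )


def _with_seed(cfg: SAConfig, seed: int) -> SAConfig:
    from dataclasses import replace

    return replace(cfg, seed=seed)


def _random_principal_submatrix(dfm: DFM, size: int, rng: np.random.Generator) -> DFM:
    """Contiguous principal submatrix of the given size at a random offset."""
    n = dfm.n_residues
    s = min(size, n)
    start = int(rng.integers(0, n - s + 1))
    sl = slice(start, start + s)
    return DFM(dfm.matrix[sl, sl].copy(), labels=dfm.labels[sl],
               source=f"{dfm.source}[{start}:{start + s}]")


def pvalue(score: float, La: int, Lb: int, model: EVDModel) -> float:
    """Gumbel upper-tail probability of reaching ``score`` under the null.

    p = 1 − exp(−exp(−(S − μ(L))/σ(L))) with L = La·Lb.  Warns (does not
    fail) when L lies outside the calibrated range; raises
    :class:`ModelRangeError` if the extrapolated scale is non-positive.
    """
    if La < 1 or Lb < 1:
        raise ValidationError("protein lengths must be >= 1")
    L = float(La) * float(Lb)
    lo, hi = model.calibrated_range
    if not lo <= L <= hi:
        warnings.warn(
            f"L={L:g} outside the calibrated range [{lo:g}, {hi:g}]; "
            "p-value is an extrapolation",
            stacklevel=2,
        )
    sigma = model.sigma(L)
    if sigma <= 0:
        raise ModelRangeError(f"model scale sigma(L) = {sigma:g} <= 0 at L = {L:g}")
    z = (score - model.mu(L)) / sigma
    # guard exp overflow for very negative z (p -> 1)
    if z < -700:
        return 1.0
    return float(-expm1(-exp(-z)))


def is_significant(p: float, threshold: float = 0.05) -> bool:
    """Strict threshold test: significantly similar iff p < threshold."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError("p must be in [0, 1]")
    return p < threshold


def synthetic_reference_dfms(
    n_refs: int,
    seed: int,
    n_frames: int = 2000,
    size_range: tuple[int, int] = (60, 110),
) -> list[DFM]:
    """Generate mutually unrelated reference DFMs from the synthetic family.

    Each reference uses an independent random-walk backbone and an
    independently drawn heterogeneous mobility profile, standing in for a
    set of evolutionarily and functionally unrelated proteins of diverse
    sizes.
    """
    from .dfm import compute_dfm
    from .synthetic import SynthSpec, generate_ensemble

    if n_refs < 4:
        raise ValidationError("need >= 4 references")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x4EF]))
    lo, hi = size_range
    sizes = np.linspace(lo, hi, n_refs).round().astype(int)
    dfms: list[DFM] = []
    for r, n in enumerate(sizes):
        mobility = _random_mobility(int(n), rng)
        spec = SynthSpec(
            n_residues=int(n),
            n_frames=n_frames,
            backbone="random_walk",
            mobility=tuple(mobility),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        ens = generate_ensemble(spec)
        dfm = compute_dfm(ens)
        dfm.source = f"synthetic-reference-{r}"
        dfms.append(dfm)
    return dfms


def _random_mobility(n: int, rng: np.random.Generator) -> np.ndarray:
    """Heterogeneous mobility with randomised loop placement and amplitude."""
    x = np.arange(n) / max(n - 1, 1)
    base = rng.uniform(0.35, 0.65)
    m = np.full(n, base)
    for _ in range(int(rng.integers(3, 6))):
        centre = rng.uniform(0.05, 0.95)
        height = rng.uniform(0.6, 1.6)
        width = rng.uniform(0.03, 0.08)
        m += height * np.exp(-0.5 * ((x - centre) / width) ** 2)
    return m
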