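"""All-vs-all dynamic similarity: score matrix, p-value matrix, similarity graph.

Every unordered pair of input DFMs is aligned once (in sorted-lexicographic
name order, with a per-pair seed derived from the master seed and the pair
names, so runs are reproducible and restartable) and its optimal score is
converted to a p-value under a calibrated Gumbel null.  Pairs with p below
the significance threshold form the edges of the dynamic similarity graph.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .align import SAConfig, anneal
from .dfm import DFM
from .errors import ValidationError
from .scoring import ScoreParams
from .significance import EVDModel, is_significant, pvalue

logger = logging.getLogger(__name__)

__all__ = ["PairResult", "run_all_vs_all", "pair_seed"]


@dataclass(frozen=True)
class PairResult:
    name_a: str
    name_b: str
    score: float
    p: float
    n_cols: int


def pair_seed(master_seed: int, name_a: str, name_b: str) -> int:
    """Deterministic per-pair seed from the master seed and pair names."""
    key = f"{master_seed}:{name_a}:{name_b}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def run_all_vs_all(
    dfms: dict[str, DFM],
    params: ScoreParams = ScoreParams(),
    cfg: SAConfig = SAConfig(),
    model: EVDModel | None = None,
    threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame | None, list[PairResult]]:
    """Align every unordered pair of DFMs and assemble similarity matrices.

    Returns (score matrix, p-value matrix, significant edges).  The p-value
    matrix and edge list require a calibrated ``model``; without one they
    are ``None`` and empty.  Matrices are symmetric with NaN diagonals.
    """
    if len(dfms) < 2:
        raise ValidationError("all-vs-all needs >= 2 DFMs")
    names = sorted(dfms)
    scores = pd.DataFrame(np.nan, index=names, columns=names)
    pvals = pd.DataFrame(np.nan, index=names, columns=names) if model else None
    edges: list[PairResult] = []
    for i, na_ in enumerate(names):
        for nb_ in names[i + 1:]:
            run_cfg = replace(cfg, seed=pair_seed(cfg.seed, na_, nb_))
            result = anneal(dfms[na_], dfms[nb_], params, run_cfg)
            s = result.best.total_score
            scores.loc[na_, nb_] = scores.loc[nb_, na_] = s
            p = np.nan
            if model is not None:
                p = pvalue(s, dfms[na_].n_residues, dfms[nb_].n_residues, model)
                pvals.loc[na_, nb_] = pvals.loc[nb_, na_] = p
                if is_significant(p, threshold):
                    edges.append(PairResult(na_, nb_, s, p, result.best.n_cols))
            logger.info("%s vs %s: score=%.2f p=%s cols=%d",
                        na_, nb_, s, f"{p:.3g}" if p == p else "n/a",
                        result.best.n_cols)
    return scores, pvals, edges
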