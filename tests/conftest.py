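import numpy as np
import pytest

from dfmalign.dfm import DFM


@pytest.fixture
def rng():
    return np.random.default_rng(20251002)


@pytest.fixture
def random_dfm(rng):
    """Factory for random valid DFMs with positive heterogeneous entries."""

    def make(n: int, scale: float = 0.5, loc: float = 1.0,
             generator: np.random.Generator | None = None) -> DFM:
        g = generator or rng
        m = np.abs(g.normal(loc, scale, (n, n)))
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 0.0)
        return DFM(m)

    return make


@pytest.fixture
def random_ensemble(rng):
    """Factory for random valid ensembles (frames x residues x 3, Å)."""

    def make(n_frames: int, n_residues: int,
             generator: np.random.Generator | None = None):
        from dfmalign.ensemble import Ensemble

        g = generator or rng
        base = g.uniform(-10, 10, (n_residues, 3))
        coords = base[None] + g.normal(0, 0.8, (n_frames, n_residues, 3))
        return Ensemble(coords)

    return make
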