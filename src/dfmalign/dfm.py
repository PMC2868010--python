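"""Dynamic Fingerprint Matrices (DFMs) and per-residue flexibility summaries.

A protein in motion cannot be described by a single distance matrix, but the
*distribution* of every inter-residue distance over a conformational ensemble
can.  The DFM collects, for every residue pair (i, j), the standard deviation
of the Cα(i)-Cα(j) distance across the frames of the ensemble.  Like a
distance matrix characterises one conformation, the DFM characterises an
ensemble — and, because pairwise distances are invariant under rigid-body
motion, it requires no superposition onto a reference structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "DFM",
    "compute_dfm",
    "dynamic_profile",
    "average_fluctuation_profile",
    "rmsf",
]


@dataclass
class DFM:
    """Symmetric matrix of pairwise Cα-distance standard deviations (Å).

    Attributes
    ----------
    matrix
        (n, n) symmetric, non-negative, zero-diagonal array.
    labels
        Residue identifiers (e.g. ``"PHE325"``), length n.
    source
        Free-text provenance (file name, generator spec, ...).
    """

    matrix: np.ndarray
    labels: list[str] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValidationError(
                f"DFM must be a square matrix, got shape {self.matrix.shape}"
            )
        n = self.matrix.shape[0]
        if not self.labels:
            self.labels = [str(i + 1) for i in range(n)]
        if len(self.labels) != n:
            raise ValidationError(
                f"{len(self.labels)} labels for a {n}x{n} matrix"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("DFM contains non-finite entries")
        scale = max(float(np.abs(self.matrix).max()), 1.0)
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9 * scale, rtol=0.0):
            raise ValidationError("DFM is not symmetric")
        if np.any(np.diag(self.matrix) != 0.0):
            raise ValidationError("DFM diagonal must be exactly zero")
        if np.any(self.matrix < 0.0):
            raise ValidationError("DFM entries must be non-negative")

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[0]

    def __len__(self) -> int:
        return self.matrix.shape[0]


def compute_dfm(ensemble, ddof: int = 0) -> DFM:
    """Compute the Dynamic Fingerprint Matrix of a conformational ensemble.

    Entry (i, j) is the standard deviation over frames of the Euclidean
    distance between Cα i and Cα j.  The diagonal is exactly zero and the
    matrix is symmetric by construction.

    Parameters
    ----------
    ensemble
        An :class:`~dfmalign.ensemble.Ensemble` (frames × residues × 3, Å).
    ddof
        Delta degrees of freedom of the standard deviation.  The default 0
        (population convention) treats the ensemble itself as the sampled
        distribution; pass 1 for the sample convention.
    """
    coords = ensemble.coords  # (F, N, 3)
    n_frames = coords.shape[0]
    if ddof not in (0, 1):
        raise ValidationError("ddof must be 0 or 1")
    if ddof == 1 and n_frames < 2:
        raise ValidationError("sample standard deviation needs >= 2 frames")
    # pairwise distances per frame: (F, N, N), computed in frame chunks to
    # bound the (F, N, N, 3) difference temporary
    n_res = coords.shape[1]
    dist = np.empty((n_frames, n_res, n_res))
    chunk = max(1, int(2e7 // (n_res * n_res * 3)))
    for start in range(0, n_frames, chunk):
        block = coords[start:start + chunk]
        diff = block[:, :, None, :] - block[:, None, :, :]
        np.sqrt(np.einsum("fijk,fijk->fij", diff, diff), out=dist[start:start + chunk])
    f = dist.std(axis=0, ddof=ddof)
    # enforce exact invariants against floating-point noise
    f = 0.5 * (f + f.T)
    np.fill_diagonal(f, 0.0)
    return DFM(f, labels=list(ensemble.residue_labels), source="compute_dfm")


def dynamic_profile(dfm: DFM, k: int) -> np.ndarray:
    """Row *k* of the DFM: how every residue fluctuates relative to residue k."""
    n = dfm.n_residues
    if not 0 <= k < n:
        raise ValidationError(f"residue index {k} out of range [0, {n})")
    return dfm.matrix[k].copy()


def average_fluctuation_profile(dfm: DFM, include_diagonal: bool = True) -> np.ndarray:
    """Per-residue mean of the DFM rows — a reference-free flexibility profile.

    With ``include_diagonal`` (default) each row mean divides by n, including
    the zero diagonal; otherwise by n − 1.  The choice rescales but never
    reorders the profile.
    """
    n = dfm.n_residues
    row_sums = dfm.matrix.sum(axis=1)
    if include_diagonal:
        return row_sums / n
    if n < 2:
        raise ValidationError("need >= 2 residues to exclude the diagonal")
    return row_sums / (n - 1)


def rmsf(ensemble, fit: bool = True, max_iter: int = 10, tol: float = 1e-10) -> np.ndarray:
    """Per-residue root mean square fluctuation of Cα about its mean position.

    With ``fit=True`` all frames are first least-squares superposed onto the
    mean structure (Kabsch), iterating mean → superpose until the mean
    converges.  ``fit=False`` uses raw coordinates, appropriate when frames
    are already aligned or when global motion is itself of interest.
    """
    coords = np.array(ensemble.coords, dtype=float, copy=True)
    if fit:
        ref = coords.mean(axis=0)
        for _ in range(max_iter):
            for f in range(coords.shape[0]):
                coords[f] = _superpose(coords[f], ref)
            new_ref = coords.mean(axis=0)
            if np.max(np.abs(new_ref - ref)) < tol:
                ref = new_ref
                break
            ref = new_ref
    mean = coords.mean(axis=0)
    dev = coords - mean  # (F, N, 3)
    return np.sqrt(np.mean(np.sum(dev * dev, axis=2), axis=0))


def _superpose(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Least-squares superposition (Kabsch) of one frame onto a reference."""
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    a = mobile - mc
    b = ref - rc
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return a @ rot + rc
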