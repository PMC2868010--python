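"""Conformational-ensemble and matrix/alignment file I/O.

Supported ensemble inputs:

* multi-model PDB files (MODEL/ENDMDL records),
* any trajectory format readable by :mod:`mdtraj` when a topology/structure
  file is supplied,
* a plain-text table dialect used by the synthetic generator and the tests:
  a header line ``#frames=<F> residues=<N>`` followed by F blocks of N
  whitespace-separated ``x y z`` lines (Å).

Only Cα atoms are extracted (one per residue); the atom selection is a
parameter so finer representations remain possible.  No superposition is
performed anywhere: the DFM is built from pairwise distances and is therefore
independent of any reference frame.

DFMs are stored as TSV with residue labels in the first row and column;
alignments as a TSV of match columns.  Residue indices are 0-based
internally and in machine-readable columns; human-facing labels carry the
author-assigned residue numbers.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dfm import DFM
from .errors import FormatError, ValidationError
from .scoring import Alignment, ScoredAlignment

logger = logging.getLogger(__name__)

__all__ = [
    "Ensemble",
    "read_ensemble",
    "write_ensemble_text",
    "read_dfm",
    "write_dfm",
    "read_alignment",
    "write_alignment",
    "read_gapped_alignment",
]


@dataclass
class Ensemble:
    """Cα coordinates of one protein chain over an ensemble of conformations.

    Attributes
    ----------
    coords
        (n_frames, n_residues, 3) array, Å.
    residue_labels
        One identifier per residue, in chain order.
    frame_interval
        Optional time between consecutive frames (ps).
    """

    coords: np.ndarray
    residue_labels: list[str] = field(default_factory=list)
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError(
                f"coords must have shape (frames, residues, 3), got {self.coords.shape}"
            )
        if self.coords.shape[0] < 2:
            raise ValidationError("an ensemble needs at least 2 frames")
        if self.coords.shape[1] < 2:
            raise ValidationError("an ensemble needs at least 2 residues")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates contain non-finite values")
        if not self.residue_labels:
            self.residue_labels = [str(i + 1) for i in range(self.coords.shape[1])]
        if len(self.residue_labels) != self.coords.shape[1]:
            raise ValidationError("residue_labels length does not match coords")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# ensemble readers
# ---------------------------------------------------------------------------

def read_ensemble(
    path: str | Path,
    topology: str | Path | None = None,
    selection: str = "name CA",
) -> Ensemble:
    """Read a conformational ensemble from a file.

    Dispatches on content/extension: the plain-text table dialect, multi-model
    PDB, or an mdtraj-readable trajectory (``topology`` required for formats
    that carry no atom names).  Returns one Cα (or ``selection``-matched atom)
    per residue per frame, in file order; residues lacking a matching atom are
    dropped with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if _looks_like_text_table(path):
        return _read_text_table(path)
    if path.suffix.lower() in (".pdb", ".ent") and topology is None:
        _check_pdb_models_consistent(path)
    return _read_with_mdtraj(path, topology, selection)


def _looks_like_text_table(path: Path) -> bool:
    try:
        with open(path, "r", errors="replace") as fh:
            first = fh.readline()
    except OSError as exc:  # pragma: no cover - filesystem errors
        raise FormatError(f"cannot read {path}: {exc}") from exc
    return first.lstrip().startswith("#frames=")


def _read_text_table(path: Path) -> Ensemble:
    with open(path) as fh:
        header = fh.readline().strip()
        try:
            fields = dict(tok.split("=") for tok in header.lstrip("#").split())
            n_frames = int(fields["frames"])
            n_res = int(fields["residues"])
        except (ValueError, KeyError) as exc:
            raise FormatError(
                f"{path}: malformed header {header!r}; expected "
                "'#frames=<F> residues=<N>'"
            ) from exc
        values = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            values.append([float(v) for v in parts])
    if len(values) != n_frames * n_res:
        raise ValidationError(
            f"{path}: header promises {n_frames}x{n_res}={n_frames * n_res} "
            f"coordinate lines, found {len(values)}"
        )
    coords = np.array(values, dtype=float).reshape(n_frames, n_res, 3)
    return Ensemble(coords)


def write_ensemble_text(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble in the plain-text table dialect (17 sig. digits)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#frames={ensemble.n_frames} residues={ensemble.n_residues}\n")
        for frame in ensemble.coords:
            for x, y, z in frame:
                fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")


def _check_pdb_models_consistent(path: Path) -> None:
    """Pre-scan a multi-model PDB so inconsistent frames raise a clear error."""
    counts: list[int] = []
    current: int | None = None
    with open(path, errors="replace") as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                current = 0
            elif rec == "ENDMDL":
                counts.append(current or 0)
                current = None
            elif rec == "ATOM" and current is not None:
                current += 1
    if current:  # trailing model without ENDMDL
        counts.append(current)
    if counts and any(c != counts[0] for c in counts):
        bad = next(i for i, c in enumerate(counts) if c != counts[0])
        raise ValidationError(
            f"{path}: model {bad + 1} has {counts[bad]} ATOM records, "
            f"model 1 has {counts[0]}; frames must share one residue set"
        )


def _read_with_mdtraj(path: Path, topology: Path | None, selection: str) -> Ensemble:
    import mdtraj  # deferred: heavy import

    try:
        if topology is not None:
            traj = mdtraj.load(str(path), top=str(topology))
        else:
            traj = mdtraj.load(str(path))
    except ValidationError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    idx = traj.topology.select(selection)
    if len(idx) == 0:
        raise ValidationError(f"{path}: selection {selection!r} matches no atoms")
    selected_res = {traj.topology.atom(int(i)).residue.index for i in idx}
    n_protein_res = traj.topology.n_residues
    dropped = n_protein_res - len(selected_res)
    if dropped > 0:
        logger.warning(
            "%s: dropped %d residue(s) without an atom matching %r",
            path, dropped, selection,
        )
    # keep first matching atom per residue, in chain order
    per_res: dict[int, int] = {}
    for i in idx:
        r = traj.topology.atom(int(i)).residue.index
        per_res.setdefault(r, int(i))
    order = sorted(per_res)
    atoms = [per_res[r] for r in order]
    labels = [
        f"{traj.topology.residue(r).name}{traj.topology.residue(r).resSeq}"
        for r in order
    ]
    coords = np.asarray(traj.xyz[:, atoms, :], dtype=float) * 10.0  # nm -> Å
    dt = float(traj.timestep) if traj.n_frames > 1 and traj.time is not None else None
    if coords.shape[0] < 2:
        raise ValidationError(f"{path}: need >= 2 frames, found {coords.shape[0]}")
    if coords.shape[1] < 2:
        raise ValidationError(
            f"{path}: need >= 2 residues after selection, found {coords.shape[1]}"
        )
    return Ensemble(coords, residue_labels=labels, frame_interval=dt)


# ---------------------------------------------------------------------------
# DFM files
# ---------------------------------------------------------------------------

def write_dfm(dfm: DFM, path: str | Path) -> None:
    """Write a DFM as a labelled TSV (round-trips to >= 12 significant digits)."""
    df = pd.DataFrame(dfm.matrix, index=dfm.labels, columns=dfm.labels)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_dfm(path: str | Path) -> DFM:
    """Read a DFM TSV, re-validating symmetry, zero diagonal and sign."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as a DFM TSV: {exc}") from exc
    matrix = df.to_numpy(dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValidationError(f"{path}: DFM must be square, got {matrix.shape}")
    labels = [str(c) for c in df.columns]
    try:
        return DFM(matrix, labels=labels, source=str(path))
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# alignment files
# ---------------------------------------------------------------------------

_ALN_COLUMNS = ["col_index", "res_a", "res_b", "label_a", "label_b"]


def write_alignment(
    aln: Alignment,
    path: str | Path,
    labels_a: list[str] | None = None,
    labels_b: list[str] | None = None,
    sms: np.ndarray | None = None,
) -> None:
    """Write an alignment TSV (residue indices 0-based; columns 1-based)."""
    rows = []
    for k, (a, b) in enumerate(aln.pairs):
        la = labels_a[a] if labels_a else str(a + 1)
        lb = labels_b[b] if labels_b else str(b + 1)
        rows.append({"col_index": k + 1, "res_a": a, "res_b": b,
                     "label_a": la, "label_b": lb})
    df = pd.DataFrame(rows, columns=_ALN_COLUMNS)
    if sms is not None:
        df["pms_sum"] = np.asarray(sms, dtype=float)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_scored_alignment(
    scored: ScoredAlignment,
    path: str | Path,
    labels_a: list[str] | None = None,
    labels_b: list[str] | None = None,
) -> None:
    write_alignment(scored.alignment, path, labels_a, labels_b, sms=scored.sms)


def read_alignment(path: str | Path) -> Alignment:
    """Read an alignment from TSV (header with res_a/res_b) or a bare
    two-column residue-index table."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=r"\s+|\t", engine="python", comment="#")
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if {"res_a", "res_b"}.issubset(df.columns):
        pairs = list(zip(df["res_a"].astype(int), df["res_b"].astype(int)))
    elif df.shape[1] >= 2 and all(
        pd.api.types.is_numeric_dtype(df[c]) for c in df.columns[:2]
    ):
        # headerless two-column table: the read above consumed row 1 as header
        df2 = pd.read_csv(path, sep=r"\s+|\t", engine="python",
                          comment="#", header=None)
        pairs = list(zip(df2.iloc[:, 0].astype(int), df2.iloc[:, 1].astype(int)))
    else:
        raise FormatError(
            f"{path}: expected columns res_a/res_b or a two-column index table"
        )
    return Alignment(pairs)


def read_gapped_alignment(path_or_text: str | Path) -> Alignment:
    """Extract match columns from a gapped pairwise sequence alignment.

    Accepts a file path or raw text containing exactly two gapped sequences,
    either as FASTA records or as two non-empty lines.  Gap characters are
    ``-`` and ``.``; a match column is one where both sequences have a
    residue, indexed by its 0-based position among that sequence's residues.
    """
    if isinstance(path_or_text, Path) or (
        isinstance(path_or_text, str) and "\n" not in path_or_text and Path(path_or_text).exists()
    ):
        text = Path(path_or_text).read_text()
    else:
        text = str(path_or_text)
    seqs = _parse_two_sequences(text)
    sa, sb = seqs
    if len(sa) != len(sb):
        raise ValidationError(
            f"gapped sequences have different lengths ({len(sa)} vs {len(sb)})"
        )
    gaps = "-."
    pairs = []
    ia = ib = 0
    for ca, cb in zip(sa, sb):
        a_res = ca not in gaps
        b_res = cb not in gaps
        if a_res and b_res:
            pairs.append((ia, ib))
        if a_res:
            ia += 1
        if b_res:
            ib += 1
    return Alignment(pairs)


def _parse_two_sequences(text: str) -> tuple[str, str]:
    lines = [ln.strip() for ln in io.StringIO(text) if ln.strip()]
    if any(ln.startswith(">") for ln in lines):
        seqs: list[str] = []
        for ln in lines:
            if ln.startswith(">"):
                seqs.append("")
            elif seqs:
                seqs[-1] += ln
        seqs = [s for s in seqs if s]
    else:
        seqs = lines
    if len(seqs) != 2:
        raise FormatError(
            f"expected exactly 2 gapped sequences, found {len(seqs)}"
        )
    return seqs[0], seqs[1]
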