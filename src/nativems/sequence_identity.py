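"""Global pairwise alignment and percent-identity computation.

For two sequences a progressive multiple-alignment program reduces to a
single global pairwise alignment, so an affine-gap Needleman-Wunsch with
the classic protein defaults (BLOSUM62, gap open 10, gap extend 0.5)
stands in for it here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = ["IdentityResult", "Scoring", "global_align", "identity_matrix",
           "write_clustal", "write_identity_matrix_tsv"]

_CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Scoring:
    """Simple substitution scoring; ``matrix=None`` means match/mismatch.

    Gap penalties are positive magnitudes; a gap of length L costs
    ``gap_open + (L - 1) * gap_extend``.
    """

    match: float = 1.0
    mismatch: float = 0.0
    gap_open: float = 10.0
    gap_extend: float = 0.5
    matrix: str | None = "BLOSUM62"


@dataclass(frozen=True)
class IdentityResult:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    n_identical: int
    alignment_length: int
    percent_identity: float


def _validate(name: str, seq: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    for pos, letter in enumerate(seq, start=1):
        if letter not in _CANONICAL:
            raise ValueError(f"{name}: unknown residue {letter!r} at position {pos}")


def _make_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if scoring.matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    else:
        aligner.match_score = scoring.match
        aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = -float(scoring.gap_open)
    aligner.extend_gap_score = -float(scoring.gap_extend)
    return aligner


def global_align(
    a: str,
    b: str,
    scoring: Scoring | None = None,
    id_a: str = "a",
    id_b: str = "b",
    denominator: str = "alignment",
) -> IdentityResult:
    """Optimal global alignment and percent identity of two sequences.

    ``denominator`` selects the identity convention: ``"alignment"``
    counts identical columns over the full alignment length including gap
    columns (the default), ``"shorter"`` divides by the shorter sequence
    length instead.
    """
    scoring = scoring or Scoring()
    _validate(id_a, a)
    _validate(id_b, b)
    if denominator not in ("alignment", "shorter"):
        raise ValueError(f"unknown denominator convention {denominator!r}")

    aligner = _make_aligner(scoring)
    alignment = next(iter(aligner.align(a, b)))  # first = deterministic choice
    aligned_a, aligned_b = alignment[0], alignment[1]
    n_identical = sum(x == y and x != "-" for x, y in zip(aligned_a, aligned_b))
    alignment_length = len(aligned_a)
    denom = alignment_length if denominator == "alignment" else min(len(a), len(b))
    return IdentityResult(
        id_a=id_a,
        id_b=id_b,
        aligned_a=str(aligned_a),
        aligned_b=str(aligned_b),
        score=float(alignment.score),
        n_identical=n_identical,
        alignment_length=alignment_length,
        percent_identity=100.0 * n_identical / denom,
    )


def identity_matrix(
    sequences: Sequence[tuple[str, str]],
    scoring: Scoring | None = None,
    denominator: str = "alignment",
) -> tuple[list[str], np.ndarray]:
    """All-vs-all percent identities for (id, sequence) pairs.

    Returns the ids (input order) and a symmetric matrix with 100 on the
    diagonal.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [sid for sid, _ in sequences]
    n = len(sequences)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            r = global_align(
                sequences[i][1], sequences[j][1], scoring,
                id_a=ids[i], id_b=ids[j], denominator=denominator,
            )
            mat[i, j] = mat[j, i] = r.percent_identity
    return ids, mat


def write_clustal(result: IdentityResult, path: str | Path, width: int = 60) -> None:
    """Write one pairwise alignment as CLUSTAL-format text."""
    name_w = max(len(result.id_a), len(result.id_b)) + 3
    lines = ["CLUSTAL format pairwise alignment", ""]
    for start in range(0, result.alignment_length, width):
        block_a = result.aligned_a[start : start + width]
        block_b = result.aligned_b[start : start + width]
        marks = "".join(
            "*" if x == y and x != "-" else " " for x, y in zip(block_a, block_b)
        )
        lines.append(f"{result.id_a:<{name_w}}{block_a}")
        lines.append(f"{result.id_b:<{name_w}}{block_b}")
        lines.append(f"{'':<{name_w}}{marks}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_identity_matrix_tsv(
    ids: Sequence[str], matrix: np.ndarray, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(ids) + "\n")
        for i, sid in enumerate(ids):
            row = "\t".join(f"{matrix[i, j]:.2f}" for j in range(len(ids)))
            fh.write(f"{sid}\t{row}\n")
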