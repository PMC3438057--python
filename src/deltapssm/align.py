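"""Affine-gap Smith–Waterman local alignment of a position score matrix
against a residue sequence.

This one engine serves both search stages: scanning a query against domain
profiles (rows = profile columns) and scanning a PSSM against database
subjects (rows = query positions).  A gap of length k costs
``gap_open + k * gap_extend``, i.e. the first gapped residue costs
open + extend (the BLAST "existence/extension" convention).

The dynamic program is the standard Gotoh three-matrix recursion with a zero
floor.  The inner loops are JIT-compiled with numba when it is available;
the identical pure-Python function is used otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LocalAlignment", "smith_waterman", "AMBIG_INDEX"]

# Ambiguous residues are encoded as index 20; callers append a 21st column of
# background-averaged scores to their score rows (see extend_rows_with_ambiguity).
AMBIG_INDEX = 20

_NEG = np.int64(-(2**40))  # effectively -infinity for gap matrices


def _sw_fill(rows, subject, gap_oe, gap_e):
    """Fill H (match), F (gap in subject / consume row) and E (gap in rows /
    consume subject) matrices.  Returns (H, E, F)."""
    l = rows.shape[0]
    n = subject.shape[0]
    H = np.zeros((l + 1, n + 1), dtype=np.int64)
    E = np.full((l + 1, n + 1), _NEG, dtype=np.int64)
    F = np.full((l + 1, n + 1), _NEG, dtype=np.int64)
    for i in range(1, l + 1):
        for j in range(1, n + 1):
            e = max(H[i, j - 1] - gap_oe, E[i, j - 1] - gap_e)
            f = max(H[i - 1, j] - gap_oe, F[i - 1, j] - gap_e)
            h = H[i - 1, j - 1] + rows[i - 1, subject[j - 1]]
            if h < 0:
                h = 0
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0:
                h = 0
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
    return H, E, F


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _sw_fill = njit(cache=True)(_sw_fill)
except ImportError:  # pragma: no cover
    pass


@dataclass
class LocalAlignment:
    """An optimal local alignment between score-matrix rows and a subject."""

    score: int
    aligned_pairs: list  # [(row_index, subject_index), ...] 0-based, monotone
    row_range: tuple  # half-open over score-matrix rows
    subject_range: tuple  # half-open over subject positions


def extend_rows_with_ambiguity(rows: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Append the background-averaged score column for ambiguous residues."""
    amb = np.rint(rows.astype(float) @ background).astype(np.int64)
    return np.concatenate([rows.astype(np.int64), amb[:, None]], axis=1)


def smith_waterman(
    score_rows: np.ndarray,
    encoded_subject: np.ndarray,
    gap_open: int,
    gap_extend: int,
) -> LocalAlignment | None:
    """Optimal affine-gap local alignment; None when the best score is <= 0.

    ``score_rows`` must have 21 columns (the last is the ambiguity column)
    and ``encoded_subject`` entries in 0..20.  The traceback is deterministic:
    the best cell is the first maximum in row-major order, and at each step
    the preference is diagonal, then up (gap in the subject), then left
    (gap in the rows).
    """
    rows = np.ascontiguousarray(score_rows, dtype=np.int64)
    subject = np.ascontiguousarray(encoded_subject, dtype=np.int64)
    if rows.shape[0] == 0 or subject.shape[0] == 0:
        return None
    gap_oe = gap_open + gap_extend
    H, E, F = _sw_fill(rows, subject, gap_oe, gap_extend)
    best = int(H.max())
    if best <= 0:
        return None
    bi, bj = np.unravel_index(int(H.argmax()), H.shape)
    i, j = int(bi), int(bj)
    pairs: list[tuple[int, int]] = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            if h == H[i - 1, j - 1] + rows[i - 1, subject[j - 1]]:
                pairs.append((i - 1, j - 1))
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in subject: consume a row
            if F[i, j] == H[i - 1, j] - gap_oe:
                state = "H"
            i -= 1
        else:  # state == "E": gap in rows: consume a subject residue
            if E[i, j] == H[i, j - 1] - gap_oe:
                state = "H"
            j -= 1
    pairs.reverse()
    return LocalAlignment(
        score=best,
        aligned_pairs=pairs,
        row_range=(pairs[0][0], pairs[-1][0] + 1),
        subject_range=(pairs[0][1], pairs[-1][1] + 1),
    )


def rescore_alignment(
    score_rows: np.ndarray,
    encoded_subject: np.ndarray,
    aligned_pairs,
    gap_open: int,
    gap_extend: int,
) -> int:
    """Recompute an alignment's raw score from its pairs plus gap penalties.

    Used by invariants/tests: for every emitted hit this must reproduce the
    DP raw score exactly.
    """

    def gap_cost(k: int) -> int:
        return 0 if k == 0 else gap_open + k * gap_extend

    total = 0
    prev = None
    for qi, sj in aligned_pairs:
        total += int(score_rows[qi, encoded_subject[sj]])
        if prev is not None:
            total -= gap_cost(qi - prev[0] - 1)
            total -= gap_cost(sj - prev[1] - 1)
        prev = (qi, sj)
    return total
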