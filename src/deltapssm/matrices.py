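"""Amino-acid alphabet, substitution-matrix data and Karlin–Altschul statistics.

Every search stage scores alignments in integer substitution-matrix units and
converts raw scores to bit scores and E-values through the Karlin–Altschul
parameters (lambda, K, H) attached to the scoring system.  The default system
is BLOSUM62 with Robinson–Robinson background frequencies and affine gap
costs of 11 (open) / 1 (per residue); its gapped parameters are shipped as
constants in the packaged data file while the ungapped lambda is re-solved at
load time and checked against the stored value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "Alphabet",
    "SubstitutionMatrix",
    "solve_ungapped_lambda",
    "evalue",
    "bit_score",
    "effective_lengths",
    "load_matrix",
    "default_matrix",
    "InvalidScoringSystemError",
]


class InvalidScoringSystemError(ValueError):
    """The score system admits no positive Karlin–Altschul lambda."""


class Alphabet:
    """The 20 canonical amino acids in NCBI matrix order.

    Ambiguity policy: non-canonical letters (X, B, Z, J, U, O, ``*`` and any
    unknown character) are encoded as -1.  During alignment they score as the
    background-weighted average of the matrix column; during PSSM
    construction they contribute zero observation counts.
    """

    RESIDUES = "ARNDCQEGHILKMFPSTWYV"
    SIZE = 20

    _INDEX = {aa: i for i, aa in enumerate(RESIDUES)}

    @classmethod
    def index(cls, letter: str) -> int:
        """Return the 0..19 index of a canonical residue, or -1."""
        return cls._INDEX.get(letter.upper(), -1)

    @classmethod
    def is_canonical(cls, letter: str) -> bool:
        return letter.upper() in cls._INDEX

    @classmethod
    def encode(cls, sequence: str) -> np.ndarray:
        """Encode a residue string as an int8 array (-1 for ambiguous)."""
        return np.fromiter(
            (cls._INDEX.get(c, -1) for c in sequence.upper()),
            dtype=np.int8,
            count=len(sequence),
        )

    @classmethod
    def decode(cls, indices) -> str:
        return "".join(cls.RESIDUES[i] if i >= 0 else "X" for i in indices)


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A 20x20 integer scoring system with its statistical parameters.

    Attributes
    ----------
    scores
        Symmetric 20x20 integer matrix in half-bit-style units.
    target_freqs
        q_ij, the joint target frequencies implied by the scores; sums to 1.
    background
        p_i, the background residue frequencies; sums to 1.
    ungapped_lambda, ungapped_K, ungapped_H
        Karlin–Altschul parameters for ungapped alignments.
    gap_open, gap_extend
        Affine gap costs: a gap of length k costs gap_open + k * gap_extend.
    gapped_lambda, gapped_K, gapped_H
        Parameters for gapped alignments at the stated gap costs.
    """

    name: str
    scores: np.ndarray
    target_freqs: np.ndarray
    background: np.ndarray
    ungapped_lambda: float
    ungapped_K: float
    ungapped_H: float
    gap_open: int
    gap_extend: int
    gapped_lambda: float
    gapped_K: float
    gapped_H: float
    ambiguity_scores: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=np.int64)
        if scores.shape != (20, 20) or not np.array_equal(scores, scores.T):
            raise ValueError("scores must be a symmetric 20x20 matrix")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if abs(self.target_freqs.sum() - 1.0) > 1e-9:
            raise ValueError("target frequencies must sum to 1")
        object.__setattr__(self, "scores", scores)
        # Score of residue i against an ambiguous residue: background-weighted
        # column average, rounded to the nearest integer.
        amb = np.rint(self.scores.astype(float) @ self.background).astype(np.int64)
        object.__setattr__(self, "ambiguity_scores", amb)

    @property
    def min_score(self) -> int:
        return int(self.scores.min())

    def expected_score(self) -> float:
        p = self.background
        return float(p @ self.scores @ p)

    def conditional_target(self) -> np.ndarray:
        """q(i|j) = q_ij / p_j: probability of residue i given aligned j."""
        return self.target_freqs / self.background[np.newaxis, :]

    def score_rows_for(self, encoded_query: np.ndarray) -> np.ndarray:
        """Per-position score rows for a query (ambiguous -> averaged column)."""
        rows = np.empty((len(encoded_query), 20), dtype=np.int64)
        for i, r in enumerate(encoded_query):
            rows[i] = self.scores[r] if r >= 0 else self.ambiguity_scores
        return rows


# ---------------------------------------------------------------------------
# Karlin–Altschul statistics
# ---------------------------------------------------------------------------

def solve_ungapped_lambda(
    matrix_scores: np.ndarray,
    background: np.ndarray,
    row_weights: np.ndarray | None = None,
    rel_tol: float = 1e-9,
) -> float:
    """Solve sum_ij w_i p_j exp(lambda * s_ij) = 1 for the positive root.

    With ``row_weights`` omitted the rows are weighted by ``background`` as
    well (the classical two-sequence case); a PSSM passes uniform weights
    over its positions.  Bracketed bisection followed by Newton polishing.

    Raises
    ------
    InvalidScoringSystemError
        If no score is positive or the expected score is non-negative, in
        which case no positive root exists.
    """
    s = np.asarray(matrix_scores, dtype=float)
    p = np.asarray(background, dtype=float)
    w = p if row_weights is None else np.asarray(row_weights, dtype=float)
    joint = w[:, None] * p[None, :]

    if not np.any(s > 0):
        raise InvalidScoringSystemError("no positive score: lambda undefined")
    expected = float((joint * s).sum())
    if expected >= 0:
        raise InvalidScoringSystemError(
            f"expected score {expected:.6g} is non-negative"
        )

    # Subtracting joint.sum() rather than 1.0 makes f(0) exactly zero, so the
    # bracketing below is immune to rounding in the normalisation of p.
    total = float(joint.sum())

    def f(lam: float) -> float:
        return float((joint * np.exp(lam * s)).sum()) - total

    # f(0)=0 with f'(0)<0; double until the sum exceeds the total again.
    hi = 0.5
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:  # pragma: no cover - guarded by preconditions
            raise InvalidScoringSystemError("failed to bracket lambda")
    lo = 0.0
    if f(hi / 2.0) > 0:
        lo = hi / 2.0
        for _ in range(200):
            if f(lo) <= 0:
                break
            lo /= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo <= rel_tol * hi:
            break
    lam = 0.5 * (lo + hi)
    # Newton polish; derivative is positive near the root.
    for _ in range(5):
        fv = f(lam)
        dv = float((joint * s * np.exp(lam * s)).sum())
        if dv <= 0:
            break
        step = fv / dv
        lam -= step
        if abs(step) <= rel_tol * lam:
            break
    return float(lam)


def relative_entropy(
    scores: np.ndarray, background: np.ndarray, lam: float
) -> float:
    """H = lambda * sum_ij q_ij s_ij with q_ij = p_i p_j exp(lambda s_ij)."""
    p = np.asarray(background, dtype=float)
    q = p[:, None] * p[None, :] * np.exp(lam * np.asarray(scores, dtype=float))
    return float(lam * (q * scores).sum())


def evalue(raw_score: float, lam: float, K: float, m: float, n: float) -> float:
    """Karlin–Altschul expected number of chance alignments: K m n e^{-lambda S}."""
    if lam <= 0 or K <= 0 or m < 1 or n < 1:
        raise ValueError("evalue requires lambda>0, K>0, m>=1, n>=1")
    return K * m * n * math.exp(-lam * raw_score)


def bit_score(raw_score: float, lam: float, K: float) -> float:
    """Normalised score (lambda*S - ln K) / ln 2."""
    return (lam * raw_score - math.log(K)) / math.log(2.0)


def effective_lengths(
    query_len: int,
    db_residues: int,
    db_seqs: int,
    lam: float,
    K: float,
    H: float,
) -> tuple[float, float]:
    """BLAST-convention edge-effect corrected search-space lengths.

    The length adjustment ell is the fixed point of

        ell = ln(K * (m - ell) * (n - N * ell)) / H

    iterated from 0 (m = query length, n = total database residues, N =
    number of database sequences), clamped so the corrected lengths stay
    positive: m_eff = max(1, m - ell), n_eff = max(N, n - N * ell).
    """
    if min(query_len, db_residues, db_seqs) < 1 or min(lam, K, H) <= 0:
        raise ValueError("effective_lengths requires positive inputs")
    m, n, N = float(query_len), float(db_residues), float(db_seqs)
    ell = 0.0
    for _ in range(50):
        m_red = max(m - ell, 1.0)
        n_red = max(n - N * ell, N)
        new = max(0.0, math.log(K * m_red * n_red) / H)
        # keep the adjustment feasible
        new = min(new, m - 1.0, (n - N) / N if n > N else 0.0)
        new = max(new, 0.0)
        if abs(new - ell) < 1e-9:
            ell = new
            break
        ell = new
    ell = math.floor(ell)
    m_eff = max(1.0, m - ell)
    n_eff = max(N, n - N * ell)
    return m_eff, n_eff


# ---------------------------------------------------------------------------
# Matrix file I/O
# ---------------------------------------------------------------------------
#
# Structured text with named blocks.  Scalars are "key: value" lines; the
# blocks "scores:", "background:" and "target_freqs:" are followed by
# whitespace-separated numeric rows (20 per row; 1 row for background,
# 20 rows otherwise).  Frequencies are printed with 17 significant digits,
# which round-trips IEEE doubles exactly.

_SCALAR_KEYS = {
    "format_version",
    "name",
    "alphabet",
    "ungapped_lambda",
    "ungapped_K",
    "ungapped_H",
    "gap_open",
    "gap_extend",
    "gapped_lambda",
    "gapped_K",
    "gapped_H",
}


def load_matrix(path: str | Path) -> SubstitutionMatrix:
    """Read a substitution-matrix data file (see module docstring)."""
    scalars: dict[str, str] = {}
    blocks: dict[str, list[list[float]]] = {}
    current: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.endswith(":") and line[:-1] in ("scores", "background", "target_freqs"):
                current = line[:-1]
                blocks[current] = []
                continue
            if ":" in line and line.split(":", 1)[0] in _SCALAR_KEYS:
                key, value = line.split(":", 1)
                scalars[key.strip()] = value.strip()
                current = None
                continue
            if current is None:
                raise ValueError(f"{path}:{lineno}: unexpected line {line!r}")
            try:
                blocks[current].append([float(x) for x in line.split()])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad numeric row") from exc

    scores = np.array(blocks["scores"], dtype=np.int64)
    background = np.array(blocks["background"], dtype=float).ravel()
    target = np.array(blocks["target_freqs"], dtype=float)
    lam_stored = float(scalars["ungapped_lambda"])
    lam = solve_ungapped_lambda(scores, background)
    if abs(lam - lam_stored) > 1e-6 * lam_stored:
        raise ValueError(
            f"stored ungapped lambda {lam_stored} disagrees with solved {lam}"
        )
    return SubstitutionMatrix(
        name=scalars.get("name", Path(path).stem),
        scores=scores,
        target_freqs=target,
        background=background,
        ungapped_lambda=lam,
        ungapped_K=float(scalars["ungapped_K"]),
        ungapped_H=float(scalars["ungapped_H"]),
        gap_open=int(scalars["gap_open"]),
        gap_extend=int(scalars["gap_extend"]),
        gapped_lambda=float(scalars["gapped_lambda"]),
        gapped_K=float(scalars["gapped_K"]),
        gapped_H=float(scalars["gapped_H"]),
    )


def write_matrix(matrix: SubstitutionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# deltapssm substitution matrix data\n")
        fh.write("format_version: 1\n")
        fh.write(f"name: {matrix.name}\n")
        fh.write(f"alphabet: {Alphabet.RESIDUES}\n")
        fh.write("scores:\n")
        for row in matrix.scores:
            fh.write(" ".join(f"{int(v):d}" for v in row) + "\n")
        fh.write("background:\n")
        fh.write(" ".join(f"{v:.17g}" for v in matrix.background) + "\n")
        fh.write("target_freqs:\n")
        for row in matrix.target_freqs:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")
        fh.write(f"ungapped_lambda: {matrix.ungapped_lambda:.17g}\n")
        fh.write(f"ungapped_K: {matrix.ungapped_K:.17g}\n")
        fh.write(f"ungapped_H: {matrix.ungapped_H:.17g}\n")
        fh.write(f"gap_open: {matrix.gap_open}\n")
        fh.write(f"gap_extend: {matrix.gap_extend}\n")
        fh.write(f"gapped_lambda: {matrix.gapped_lambda:.17g}\n")
        fh.write(f"gapped_K: {matrix.gapped_K:.17g}\n")
        fh.write(f"gapped_H: {matrix.gapped_H:.17g}\n")


@lru_cache(maxsize=1)
def default_matrix() -> SubstitutionMatrix:
    """BLOSUM62 with Robinson–Robinson backgrounds and 11/1 gap costs."""
    ref = resources.files("deltapssm").joinpath("data/blosum62.txt")
    with resources.as_file(ref) as path:
        return load_matrix(path)
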