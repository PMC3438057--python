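"""Construction of a query PSSM from domain-profile hits.

The pipeline collapses the query's profile alignments onto the query
template, estimates per-position observed frequencies weighted by effective
observation counts, mixes them with data-dependent pseudocounts, converts
target-to-background frequency ratios into scores of the form (ln R_i)/λ,
and rescales the integer matrix so its Karlin–Altschul lambda matches the
underlying substitution matrix (which lets the matrix's precomputed gapped
parameters be reused for E-values).

Column bookkeeping rules:

* profile columns aligned to gaps inserted into the query are discarded
  (the query is the MSA template);
* if the same profile aligns more than once to a query column, only the
  lowest-E-value alignment contributes there;
* the query residue itself enters with a single observation only where its
  residue has zero weighted frequency among the contributing profile
  columns, so large well-modelled families are not diluted while every
  query position still receives some evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from deltapssm.matrices import (
    Alphabet,
    InvalidScoringSystemError,
    SubstitutionMatrix,
    solve_ungapped_lambda,
)
from deltapssm.profiles import ProfileLibrary

__all__ = [
    "CollapsedColumn",
    "Pssm",
    "collapse",
    "observed_frequencies",
    "target_frequencies",
    "pssm_scores",
    "scale_pssm",
    "build_pssm",
    "write_pssm",
    "read_pssm",
    "export_ascii_pssm",
]

DEFAULT_PSEUDOCOUNT = 10.0  # beta: the classic PSI-BLAST pseudocount weight


@dataclass
class Contribution:
    profile_id: str
    profile_col: int
    freqs: np.ndarray  # 20-vector
    weight: float  # effective observations of that profile column
    evalue: float
    raw_score: int


@dataclass
class CollapsedColumn:
    """One query position after merging aligned domain columns."""

    query_pos: int
    query_residue: str
    contributions: list  # of Contribution, at most one per profile id
    query_included: bool = True


@dataclass
class Pssm:
    """An l x 20 integer position-specific score matrix with statistics.

    ``scores`` are integers at ``scale`` units per matrix unit; raw alignment
    scores computed from them must therefore be combined with
    ``gapped_lambda`` (already divided by the scale) and ``gapped_K``.
    """

    query_id: str
    query: str
    scores: np.ndarray  # l x 20 int
    target_freqs: np.ndarray  # l x 20
    alpha: np.ndarray  # l vector of data weights (N_c - 1)
    lambda_: float  # per-unit lambda used to derive the scores
    gapped_lambda: float
    gapped_K: float
    gapped_H: float
    gap_open: int
    gap_extend: int
    background: np.ndarray = None  # 20-vector used for ambiguity scoring
    scale: int = 1
    provenance: list = field(default_factory=list)  # per column: [profile ids]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.background is None:
            comp = np.asarray(self.target_freqs, dtype=float).mean(axis=0)
            self.background = comp / comp.sum()

    @property
    def length(self) -> int:
        return len(self.scores)


# ---------------------------------------------------------------------------
# Collapse profile hits onto the query template
# ---------------------------------------------------------------------------

def collapse(query: str, hits, library: ProfileLibrary) -> list[CollapsedColumn]:
    """Merge profile hits into one collapsed column per query position.

    Insertions relative to the query never appear because hits carry only
    (query_pos, profile_col) matched pairs; unmatched profile columns are
    exactly the ones aligned to query gaps and are ignored.  Per-column
    conflicts between alignments of the same profile are resolved by lowest
    E-value, then larger raw score, then smaller profile column index.
    """
    # per query position: profile_id -> best Contribution
    best: list[dict] = [dict() for _ in query]
    for hit in hits:
        if hit.profile_id not in library.profiles:
            raise KeyError(f"hit references unknown profile {hit.profile_id!r}")
        profile = library[hit.profile_id]
        for qpos, pcol in hit.aligned_pairs:
            freqs = profile.freqs[pcol]
            if freqs.sum() <= 0:  # gap-only profile column: no evidence
                continue
            cand = Contribution(
                profile_id=hit.profile_id,
                profile_col=pcol,
                freqs=freqs,
                weight=float(profile.n_obs[pcol]),
                evalue=hit.evalue,
                raw_score=hit.raw_score,
            )
            cur = best[qpos].get(hit.profile_id)
            if cur is None or _better(cand, cur):
                best[qpos][hit.profile_id] = cand
    columns = []
    for pos, residue in enumerate(query):
        contribs = [best[pos][pid] for pid in sorted(best[pos])]
        ridx = Alphabet.index(residue)
        if ridx >= 0:
            observed = sum(c.weight * c.freqs[ridx] for c in contribs)
            included = observed == 0.0
        else:
            included = False  # ambiguous query residues contribute no counts
        columns.append(
            CollapsedColumn(
                query_pos=pos,
                query_residue=residue,
                contributions=contribs,
                query_included=included,
            )
        )
    return columns


def _better(a: Contribution, b: Contribution) -> bool:
    ka = (a.evalue, -a.raw_score, a.profile_col)
    kb = (b.evalue, -b.raw_score, b.profile_col)
    return ka < kb


def observed_frequencies(
    column: CollapsedColumn, background: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Weighted observed frequencies f (sums to 1) and data weight alpha.

    f is the observation-weighted mixture of the contributing profile
    columns, plus a unit point mass on the query residue where it is
    included; alpha is (total observation weight) - 1, floored at zero.  An
    ambiguous query residue with no contributions falls back to the
    background distribution (zero observations).
    """
    f = np.zeros(20)
    total = 0.0
    for c in column.contributions:
        f += c.weight * c.freqs
        total += c.weight
    ridx = Alphabet.index(column.query_residue)
    if column.query_included and ridx >= 0:
        f[ridx] += 1.0
        total += 1.0
    if total <= 0:
        if background is None:
            raise ValueError(
                f"column {column.query_pos}: no observations and no background"
            )
        return np.asarray(background, dtype=float).copy(), 0.0
    return f / f.sum(), max(total - 1.0, 0.0)


# ---------------------------------------------------------------------------
# Data-dependent pseudocounts and scores
# ---------------------------------------------------------------------------

def target_frequencies(
    f: np.ndarray,
    alpha: float,
    matrix: SubstitutionMatrix,
    beta: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Mix observed frequencies with data-dependent pseudocounts.

    The pseudocount distribution g_i = sum_j (f_j / p_j) q_ij (normalised)
    spreads each observed residue over its substitution-matrix neighbourhood;
    the target is Q = (alpha f + beta g) / (alpha + beta), so alpha = 0
    returns the pure prior and alpha -> infinity returns f.
    """
    if alpha < 0 or beta <= 0:
        raise ValueError("alpha must be >= 0 and beta > 0")
    f = np.asarray(f, dtype=float)
    g = matrix.target_freqs @ (f / matrix.background)
    g = g / g.sum()
    q = (alpha * f + beta * g) / (alpha + beta)
    return q / q.sum()


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def pssm_scores(
    q_rows: np.ndarray,
    background: np.ndarray,
    lambda_u: float,
    scale: int = 1,
    floor_score: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Scores s_ij = round(scale * ln(Q_ij / p_j) / lambda_u).

    Returns (integer scores, real-valued scores before rounding).  A zero
    target frequency maps to ``floor_score`` (in matrix units, scaled).
    Rounding is to the nearest integer with ties away from zero.
    """
    q = np.asarray(q_rows, dtype=float)
    p = np.asarray(background, dtype=float)
    with np.errstate(divide="ignore"):
        real = np.log(q / p[np.newaxis, :]) / lambda_u
    if floor_score is not None:
        real = np.where(q <= 0, float(floor_score), real)
    elif not np.all(q > 0):
        raise ValueError("zero target frequency requires a floor score")
    real = real * scale
    return _round_half_away(real).astype(np.int64), real


def pssm_ungapped_lambda(scores: np.ndarray, background: np.ndarray) -> float:
    """Karlin–Altschul lambda of a PSSM, averaging uniformly over positions."""
    l = len(scores)
    weights = np.full(l, 1.0 / l)
    return solve_ungapped_lambda(scores, background, row_weights=weights)


def scale_pssm(
    real_scores: np.ndarray,
    matrix: SubstitutionMatrix,
    scale: int = 1,
) -> tuple[np.ndarray, float]:
    """Rescale a real-valued PSSM so its ungapped lambda matches the matrix.

    For real-valued scores lambda(c * S) = lambda(S) / c, so the multiplier
    c = lambda(S) / lambda_u makes the rescaled matrix's lambda equal the
    substitution matrix's ungapped lambda exactly (before integer rounding);
    the matrix's precomputed gapped (lambda_g, K_g) then apply to the rounded
    scores.  Returns (integer scores at ``scale`` units, c).

    Raises
    ------
    InvalidScoringSystemError
        If the PSSM has non-negative expected score against the background
        (no valid lambda).
    """
    real = np.asarray(real_scores, dtype=float)
    lam = pssm_ungapped_lambda(real, matrix.background)
    c = lam / matrix.ungapped_lambda
    scaled = real * c * scale
    return _round_half_away(scaled).astype(np.int64), float(c)


# ---------------------------------------------------------------------------
# End-to-end construction
# ---------------------------------------------------------------------------

def build_pssm(
    query: str,
    library: ProfileLibrary | None,
    matrix: SubstitutionMatrix,
    query_id: str = "query",
    hits=None,
    beta: float = DEFAULT_PSEUDOCOUNT,
    scale: int = 1,
    inclusion_evalue: float = 0.05,
    min_max_obs: float = 6.0,
) -> Pssm:
    """Build the domain-enhanced PSSM for a query.

    When ``hits`` is None the library is searched first
    (:func:`deltapssm.domain_search.search_domains`); pass an explicit
    (possibly empty) hit list to skip that stage.  Zero hits is not an
    error: the result is the query-only PSSM whose rows reproduce the
    substitution-matrix rows (the BLASTP fallback identity).
    """
    if not query:
        raise ValueError("empty query")
    if hits is None:
        from deltapssm.domain_search import search_domains

        if library is not None and len(library) > 0:
            hits = search_domains(
                query,
                library,
                matrix,
                inclusion_evalue=inclusion_evalue,
                min_max_obs=min_max_obs,
                beta=beta,
            )
        else:
            hits = []
    columns = collapse(query, hits, library if library is not None else ProfileLibrary())
    l = len(query)
    q_rows = np.empty((l, 20))
    alphas = np.empty(l)
    provenance = []
    for col in columns:
        f, alpha = observed_frequencies(col, matrix.background)
        q_rows[col.query_pos] = target_frequencies(f, alpha, matrix, beta)
        alphas[col.query_pos] = alpha
        provenance.append([c.profile_id for c in col.contributions])
    floor = matrix.min_score - 1
    _, real = pssm_scores(
        q_rows, matrix.background, matrix.ungapped_lambda, scale=1, floor_score=floor
    )
    scores, c = scale_pssm(real, matrix, scale=scale)
    return Pssm(
        query_id=query_id,
        query=query,
        scores=scores,
        target_freqs=q_rows,
        alpha=alphas,
        lambda_=matrix.ungapped_lambda / scale,
        gapped_lambda=matrix.gapped_lambda / scale,
        gapped_K=matrix.gapped_K,
        gapped_H=matrix.gapped_H,
        gap_open=matrix.gap_open * scale,
        gap_extend=matrix.gap_extend * scale,
        background=matrix.background.copy(),
        scale=scale,
        provenance=provenance,
        metadata={
            "n_hits": len(hits),
            "fallback": len(hits) == 0,
            "beta": beta,
            "scale_multiplier": c,
            "contributing_profiles": sorted({h.profile_id for h in hits}),
        },
    )


# ---------------------------------------------------------------------------
# PSSM I/O
# ---------------------------------------------------------------------------

def write_pssm(pssm: Pssm, path: str | Path) -> None:
    """Write the structured-text PSSM dialect (scores, targets, provenance)."""
    with open(path, "w") as fh:
        fh.write("# deltapssm PSSM\n")
        fh.write("format_version: 1\n")
        fh.write(f"query_id: {pssm.query_id}\n")
        fh.write(f"query: {pssm.query}\n")
        fh.write(f"length: {pssm.length}\n")
        fh.write(f"scale: {pssm.scale}\n")
        fh.write(f"lambda: {pssm.lambda_:.17g}\n")
        fh.write(f"gapped_lambda: {pssm.gapped_lambda:.17g}\n")
        fh.write(f"gapped_K: {pssm.gapped_K:.17g}\n")
        fh.write(f"gapped_H: {pssm.gapped_H:.17g}\n")
        fh.write(f"gap_open: {pssm.gap_open}\n")
        fh.write(f"gap_extend: {pssm.gap_extend}\n")
        fh.write("alpha: " + " ".join(f"{a:.10g}" for a in pssm.alpha) + "\n")
        fh.write(
            "background: " + " ".join(f"{v:.17g}" for v in pssm.background) + "\n"
        )
        fh.write("scores:\n")
        for row in pssm.scores:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")
        fh.write("target_freqs:\n")
        for row in pssm.target_freqs:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
        fh.write("provenance:\n")
        for ids in pssm.provenance:
            fh.write((",".join(ids) if ids else ".") + "\n")
        fh.write("end\n")


def read_pssm(path: str | Path) -> Pssm:
    scalars: dict[str, str] = {}
    blocks: dict[str, list] = {"scores": [], "target_freqs": [], "provenance": []}
    current = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").strip()
            if not line or line.startswith("#"):
                continue
            if line == "end":
                current = None
                continue
            if line.endswith(":") and line[:-1] in blocks:
                current = line[:-1]
                continue
            if current == "provenance":
                blocks[current].append([] if line == "." else line.split(","))
                continue
            if current is not None:
                try:
                    blocks[current].append([float(x) for x in line.split()])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad numeric row") from exc
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: unexpected line {line!r}")
            key, value = line.split(":", 1)
            scalars[key.strip()] = value.strip()
    scores = np.array(blocks["scores"], dtype=np.int64)
    return Pssm(
        query_id=scalars["query_id"],
        query=scalars["query"],
        scores=scores,
        target_freqs=np.array(blocks["target_freqs"], dtype=float),
        alpha=np.array([float(x) for x in scalars["alpha"].split()]),
        lambda_=float(scalars["lambda"]),
        gapped_lambda=float(scalars["gapped_lambda"]),
        gapped_K=float(scalars["gapped_K"]),
        gapped_H=float(scalars["gapped_H"]),
        gap_open=int(scalars["gap_open"]),
        gap_extend=int(scalars["gap_extend"]),
        background=np.array([float(x) for x in scalars["background"].split()]),
        scale=int(scalars["scale"]),
        provenance=blocks["provenance"],
    )


def export_ascii_pssm(pssm: Pssm, path: str | Path) -> None:
    """Write a BLAST-style ASCII PSSM table (position, residue, 20 scores)."""
    with open(path, "w") as fh:
        fh.write("# position-specific scoring matrix (matrix units x scale)\n")
        fh.write("     " + "  ".join(f"{a:>3s}" for a in Alphabet.RESIDUES) + "\n")
        for i, row in enumerate(pssm.scores, start=1):
            fh.write(
                f"{i:4d} {pssm.query[i - 1]} "
                + " ".join(f"{int(v):4d}" for v in row)
                + "\n"
            )
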