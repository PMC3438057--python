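"""Search a query sequence against a domain-profile library.

Each retained profile is converted to a position score matrix (the same
pseudocount and scaling machinery used for query PSSMs, with the per-column
data weight alpha = N_c - 1) and aligned to the query by exhaustive
affine-gap Smith–Waterman — identical optima to a word-seeded profile scan
at desk scale.  Two inclusion rules gate the results: profiles whose maximum
effective observation count over all columns is below ``min_max_obs``
(default 6) are never aligned, because their PSSMs would be too narrowly
focused; and alignments with E-value above ``inclusion_evalue`` (default
0.05) are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from deltapssm.align import (
    AMBIG_INDEX,
    extend_rows_with_ambiguity,
    smith_waterman,
)
from deltapssm.matrices import (
    Alphabet,
    SubstitutionMatrix,
    bit_score,
    effective_lengths,
    evalue,
)
from deltapssm.profiles import DomainProfile, ProfileLibrary
from deltapssm.pssm import (
    DEFAULT_PSEUDOCOUNT,
    pssm_scores,
    scale_pssm,
    target_frequencies,
)

__all__ = ["ProfileHit", "profile_scores", "align_query_to_profile", "search_domains"]

DEFAULT_INCLUSION_EVALUE = 0.05
DEFAULT_MIN_MAX_OBS = 6.0

_MASK_SCORE = -(10**6)


@dataclass
class ProfileHit:
    """A local alignment between the query and one domain profile."""

    query_id: str
    profile_id: str
    raw_score: int
    bit_score: float
    evalue: float
    aligned_pairs: list  # [(query_pos, profile_col)], strictly increasing
    query_range: tuple  # half-open
    profile_range: tuple  # half-open


def profile_scores(
    profile: DomainProfile,
    matrix: SubstitutionMatrix,
    beta: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[np.ndarray, np.ndarray]:
    """Integer score rows for a profile's non-degenerate columns.

    Returns (scores: k x 20 integers, col_index: k-vector mapping score rows
    back to original profile columns).  Gap-only columns are skipped.  The
    rows are rescaled so the matrix's Karlin–Altschul parameters apply
    (see :func:`deltapssm.pssm.scale_pssm`).
    """
    cols = profile.nondegenerate_columns()
    if len(cols) == 0:
        raise ValueError(f"profile {profile.id}: all columns are gap-only")
    q_rows = np.empty((len(cols), 20))
    for k, col in enumerate(cols):
        alpha = max(float(profile.n_obs[col]) - 1.0, 0.0)
        q_rows[k] = target_frequencies(profile.freqs[col], alpha, matrix, beta)
    floor = matrix.min_score - 1
    _, real = pssm_scores(
        q_rows, matrix.background, matrix.ungapped_lambda, scale=1, floor_score=floor
    )
    scores, _ = scale_pssm(real, matrix)
    return scores, cols


def align_query_to_profile(
    query: str,
    scores: np.ndarray,
    col_index: np.ndarray,
    gap_open: int,
    gap_extend: int,
    background: np.ndarray,
) -> tuple[int, list] | None:
    """Best affine-gap local alignment of the query against profile scores.

    Returns (raw_score, [(query_pos, profile_col), ...]) or None when no
    alignment scores above zero.  The DP rows are the profile columns and
    the subject is the query, so ties prefer the diagonal, then consuming a
    profile column, then consuming a query residue.
    """
    encoded = Alphabet.encode(query)
    encoded = np.where(encoded < 0, AMBIG_INDEX, encoded).astype(np.int64)
    rows = extend_rows_with_ambiguity(scores, background)
    aln = smith_waterman(rows, encoded, gap_open, gap_extend)
    if aln is None:
        return None
    pairs = [(int(j), int(col_index[i])) for i, j in aln.aligned_pairs]
    return aln.score, pairs


def search_domains(
    query: str,
    library: ProfileLibrary,
    matrix: SubstitutionMatrix,
    inclusion_evalue: float = DEFAULT_INCLUSION_EVALUE,
    min_max_obs: float = DEFAULT_MIN_MAX_OBS,
    beta: float = DEFAULT_PSEUDOCOUNT,
    max_hsps: int = 1,
    query_id: str = "query",
) -> list[ProfileHit]:
    """Align the query to every sufficiently diverse profile and filter hits.

    Profiles with max(n_obs) < ``min_max_obs`` are excluded before any
    alignment; hits with E-value above ``inclusion_evalue`` are dropped.
    The search space for E-values treats the filtered library as one
    database: n = total number of profile columns, N = number of profiles.
    With ``max_hsps`` > 1, up to that many non-overlapping alignments per
    profile are returned by iteratively masking the profile columns already
    used.
    """
    if not query:
        raise ValueError("empty query")
    if len(library) == 0:
        raise ValueError("empty profile library")
    retained = [p for p in library if p.max_obs >= min_max_obs]
    if not retained:
        return []
    total_cols = sum(p.length for p in retained)
    m_eff, n_eff = effective_lengths(
        len(query),
        total_cols,
        len(retained),
        matrix.gapped_lambda,
        matrix.gapped_K,
        matrix.gapped_H,
    )
    hits: list[ProfileHit] = []
    for profile in retained:
        scores, cols = profile_scores(profile, matrix, beta)
        work = scores.copy()
        for _ in range(max_hsps):
            result = align_query_to_profile(
                query, work, cols, matrix.gap_open, matrix.gap_extend,
                matrix.background,
            )
            if result is None:
                break
            raw, pairs = result
            ev = evalue(raw, matrix.gapped_lambda, matrix.gapped_K, m_eff, n_eff)
            if ev <= inclusion_evalue:
                qpos = [p[0] for p in pairs]
                pcol = [p[1] for p in pairs]
                hits.append(
                    ProfileHit(
                        query_id=query_id,
                        profile_id=profile.id,
                        raw_score=raw,
                        bit_score=bit_score(raw, matrix.gapped_lambda, matrix.gapped_K),
                        evalue=ev,
                        aligned_pairs=pairs,
                        query_range=(min(qpos), max(qpos) + 1),
                        profile_range=(min(pcol), max(pcol) + 1),
                    )
                )
            # mask the used profile columns for further HSPs
            used = {p[1] for p in pairs}
            row_of = {int(c): k for k, c in enumerate(cols)}
            for col in used:
                work[row_of[col]] = _MASK_SCORE
    hits.sort(key=lambda h: (h.evalue, h.profile_id))
    return hits
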