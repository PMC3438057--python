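"""Search a protein FASTA database with a PSSM (or the plain matrix).

Every subject is aligned against the PSSM rows by full affine-gap
Smith–Waterman; E-values use the gapped Karlin–Altschul parameters attached
to the PSSM together with BLAST-convention effective lengths.  The BLASTP
fallback uses the substitution-matrix rows of the query instead of a PSSM
and is hit-for-hit equivalent to searching with the query-only PSSM.

Output dialects: 12-column BLAST tabular (qseqid sseqid pident length
mismatch gapopen qstart qend sstart send evalue bitscore, 1-based inclusive
coordinates) and a JSON-lines dialect carrying the aligned pairs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from deltapssm.align import (
    AMBIG_INDEX,
    extend_rows_with_ambiguity,
    smith_waterman,
)
from deltapssm.matrices import Alphabet, SubstitutionMatrix, effective_lengths, evalue
from deltapssm.pssm import Pssm

__all__ = [
    "SearchHit",
    "read_fasta",
    "search_database",
    "blastp_fallback",
    "write_tabular",
    "write_jsonl",
    "read_tabular",
]

DEFAULT_REPORT_EVALUE = 10.0


@dataclass
class SearchHit:
    """One query-subject local alignment with scores and statistics."""

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    identity_fraction: float
    aligned_pairs: list  # [(query_pos, subject_pos)] 0-based, monotone
    query_range: tuple  # half-open
    subject_range: tuple  # half-open
    is_self: bool = False

    # alignment summary counts for the tabular report
    @property
    def n_identical(self) -> int:
        return round(self.identity_fraction * len(self.aligned_pairs))


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file as (id, sequence); id is the header up to whitespace."""
    try:
        records = [
            (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
        ]
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read FASTA {path}: {exc}") from exc
    if not records:
        raise OSError(f"cannot read FASTA {path}: no records")
    return records


def _encode(sequence: str) -> np.ndarray:
    enc = Alphabet.encode(sequence)
    return np.where(enc < 0, AMBIG_INDEX, enc).astype(np.int64)


def _gap_openings(pairs) -> int:
    opens = 0
    prev = None
    for qi, sj in pairs:
        if prev is not None:
            if qi - prev[0] > 1:
                opens += 1
            if sj - prev[1] > 1:
                opens += 1
        prev = (qi, sj)
    return opens


def _search_with_rows(
    rows: np.ndarray,
    query_id: str,
    query_seq: str,
    db_records,
    gapped_lambda: float,
    gapped_K: float,
    gapped_H: float,
    gap_open: int,
    gap_extend: int,
    background: np.ndarray,
    report_evalue: float,
) -> list[SearchHit]:
    db_residues = sum(len(s) for _, s in db_records)
    m_eff, n_eff = effective_lengths(
        len(query_seq), db_residues, len(db_records), gapped_lambda, gapped_K, gapped_H
    )
    ext_rows = extend_rows_with_ambiguity(rows, background)
    hits: list[SearchHit] = []
    for subject_id, subject_seq in db_records:
        if not subject_seq:
            continue
        encoded = _encode(subject_seq)
        aln = smith_waterman(ext_rows, encoded, gap_open, gap_extend)
        if aln is None:
            continue
        ev = evalue(aln.score, gapped_lambda, gapped_K, m_eff, n_eff)
        if ev > report_evalue:
            continue
        pairs = [(int(i), int(j)) for i, j in aln.aligned_pairs]
        n_ident = sum(1 for qi, sj in pairs if query_seq[qi] == subject_seq[sj])
        hits.append(
            SearchHit(
                query_id=query_id,
                subject_id=subject_id,
                raw_score=aln.score,
                bit_score=(gapped_lambda * aln.score - math.log(gapped_K))
                / math.log(2.0),
                evalue=ev,
                identity_fraction=n_ident / len(pairs),
                aligned_pairs=pairs,
                query_range=aln.row_range,
                subject_range=aln.subject_range,
                is_self=subject_id == query_id,
            )
        )
    hits.sort(key=lambda h: (h.evalue, -h.bit_score, h.subject_id))
    return hits


def search_database(
    pssm: Pssm,
    db: str | Path | list,
    report_evalue: float = DEFAULT_REPORT_EVALUE,
) -> list[SearchHit]:
    """Rank all database subjects against the PSSM by E-value.

    ``db`` is a FASTA path or a pre-loaded list of (id, sequence) records.
    Hits are sorted by E-value ascending, ties by bit score descending then
    subject id; subjects whose best alignment scores zero are absent.
    """
    records = db if isinstance(db, list) else read_fasta(db)
    return _search_with_rows(
        pssm.scores,
        pssm.query_id,
        pssm.query,
        records,
        pssm.gapped_lambda,
        pssm.gapped_K,
        pssm.gapped_H,
        pssm.gap_open,
        pssm.gap_extend,
        pssm.background,
        report_evalue,
    )


def blastp_fallback(
    query: str,
    db: str | Path | list,
    matrix: SubstitutionMatrix,
    report_evalue: float = DEFAULT_REPORT_EVALUE,
    query_id: str = "query",
) -> list[SearchHit]:
    """Plain matrix search: the route taken when no domain profile matched."""
    if not query:
        raise ValueError("empty query")
    records = db if isinstance(db, list) else read_fasta(db)
    rows = matrix.score_rows_for(Alphabet.encode(query))
    return _search_with_rows(
        rows,
        query_id,
        query,
        records,
        matrix.gapped_lambda,
        matrix.gapped_K,
        matrix.gapped_H,
        matrix.gap_open,
        matrix.gap_extend,
        matrix.background,
        report_evalue,
    )


# ---------------------------------------------------------------------------
# Report formats
# ---------------------------------------------------------------------------

def write_tabular(hits: list[SearchHit], path: str | Path) -> None:
    """BLAST outfmt-6-style TSV; coordinates 1-based inclusive."""
    with open(path, "w") as fh:
        for h in hits:
            length = len(h.aligned_pairs)
            mismatch = length - h.n_identical
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{100.0 * h.identity_fraction:.2f}",
                        str(length),
                        str(mismatch),
                        str(_gap_openings(h.aligned_pairs)),
                        str(h.query_range[0] + 1),
                        str(h.query_range[1]),
                        str(h.subject_range[0] + 1),
                        str(h.subject_range[1]),
                        f"{h.evalue:.3g}",
                        f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )


def write_jsonl(hits: list[SearchHit], path: str | Path) -> None:
    """Extended JSON-lines dialect with the aligned pairs."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                json.dumps(
                    {
                        "query_id": h.query_id,
                        "subject_id": h.subject_id,
                        "raw_score": h.raw_score,
                        "bit_score": h.bit_score,
                        "evalue": h.evalue,
                        "identity_fraction": h.identity_fraction,
                        "query_range": list(h.query_range),
                        "subject_range": list(h.subject_range),
                        "aligned_pairs": [list(p) for p in h.aligned_pairs],
                        "is_self": h.is_self,
                    }
                )
                + "\n"
            )


def read_tabular(path: str | Path) -> list[dict]:
    """Read the 12-column tabular dialect back as dictionaries."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                {
                    "query_id": f[0],
                    "subject_id": f[1],
                    "pident": float(f[2]),
                    "length": int(f[3]),
                    "evalue": float(f[10]),
                    "bit_score": float(f[11]),
                }
            )
    return out
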