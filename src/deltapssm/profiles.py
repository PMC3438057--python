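"""Conserved-domain profiles: per-column weighted residue frequencies plus
effective independent observations, built from multiple sequence alignments.

A profile column carries (i) the weighted observed frequencies of the 20
amino acids among the aligned sequences and (ii) an effective number of
independent observations N_c >= 1, a measure of how much genuinely
independent evidence the column holds.  N_c - 1 later becomes the data
weight in the pseudocount mix.  Effective observations are estimated in the
PSI-BLAST lineage: the mean number of distinct residue types per column
(over the column's containing block of identically-populated columns) is
mapped back to an observation count by inverting the expected number of
distinct types seen in N independent draws from the background,

    E[distinct | N] = sum_i (1 - (1 - p_i)^N),

which is smooth and increasing in N, so the inversion is a 1-d root find.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from scipy.optimize import brentq

from deltapssm.matrices import Alphabet, SubstitutionMatrix

__all__ = [
    "DomainProfile",
    "ProfileLibrary",
    "sequence_weights",
    "effective_observations",
    "build_profile",
    "read_msa_fasta",
    "read_library",
    "write_library",
]

GAP_CHARS = set("-.")

FORMAT_VERSION = 1
# Frequencies and observation counts are printed with 10 significant digits;
# this is the format's documented round-trip precision.
_FREQ_FMT = "%.10g"


@dataclass
class DomainProfile:
    """A conserved-domain model: column frequencies + observation counts.

    A column that contained only gaps in the source MSA is stored as an
    all-zero frequency row (consensus '-') and is skipped during alignment.
    """

    id: str
    freqs: np.ndarray  # length x 20, rows sum to 1 or are all zero
    n_obs: np.ndarray  # length vector, all >= 1
    consensus: str = ""
    description: str = ""

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.n_obs = np.asarray(self.n_obs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 20 or len(self.freqs) < 1:
            raise ValueError(f"profile {self.id}: freqs must be length x 20")
        if len(self.n_obs) != len(self.freqs):
            raise ValueError(f"profile {self.id}: n_obs length mismatch")
        if np.any(self.n_obs < 1.0 - 1e-12):
            raise ValueError(f"profile {self.id}: n_obs must be >= 1")
        sums = self.freqs.sum(axis=1)
        bad = ~((np.abs(sums - 1.0) <= 1e-9) | (sums == 0.0))
        if bad.any():
            raise ValueError(f"profile {self.id}: non-normalised frequency row")
        if not self.consensus:
            self.consensus = "".join(
                Alphabet.RESIDUES[int(r.argmax())] if r.sum() > 0 else "-"
                for r in self.freqs
            )

    @property
    def length(self) -> int:
        return len(self.freqs)

    @property
    def max_obs(self) -> float:
        return float(self.n_obs.max())

    def nondegenerate_columns(self) -> np.ndarray:
        """Indices of columns that carry observations (non-gap-only)."""
        return np.nonzero(self.freqs.sum(axis=1) > 0)[0]


@dataclass
class ProfileLibrary:
    """A collection of domain profiles with optional superfamily grouping."""

    profiles: dict = field(default_factory=dict)  # id -> DomainProfile
    superfamily_of: dict = field(default_factory=dict)  # id -> superfamily id

    def add(self, profile: DomainProfile, superfamily: str | None = None) -> None:
        if profile.id in self.profiles:
            raise ValueError(f"duplicate profile id {profile.id!r}")
        self.profiles[profile.id] = profile
        if superfamily is not None:
            self.superfamily_of[profile.id] = superfamily

    def __len__(self) -> int:
        return len(self.profiles)

    def __getitem__(self, pid: str) -> DomainProfile:
        return self.profiles[pid]

    def __iter__(self):
        return iter(self.profiles.values())


# ---------------------------------------------------------------------------
# MSA handling
# ---------------------------------------------------------------------------

def read_msa_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA file ('-' gaps) as (id, row) tuples."""
    rows = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise ValueError(f"{path}: empty alignment")
    lengths = {len(r) for _, r in rows}
    if len(lengths) != 1:
        raise ValueError(f"{path}: rows have unequal lengths {sorted(lengths)}")
    return rows


def _column_residues(rows: list[str], col: int) -> list[int]:
    """Canonical residue indices present in a column (gaps/ambiguous excluded)."""
    out = []
    for row in rows:
        c = row[col]
        if c in GAP_CHARS:
            continue
        idx = Alphabet.index(c)
        if idx >= 0:
            out.append(idx)
    return out


def sequence_weights(msa_rows: list[str]) -> np.ndarray:
    """Henikoff position-based sequence weights, normalised to sum to 1.

    Only columns containing at least two distinct residue types contribute;
    within such a column a sequence holding residue r gains 1/(r_types *
    n_with_r).  If no column is informative, weights are uniform.
    """
    if not msa_rows:
        raise ValueError("empty MSA")
    k = len(msa_rows)
    ncol = len(msa_rows[0])
    w = np.zeros(k)
    for col in range(ncol):
        residues = [
            Alphabet.index(row[col]) if row[col] not in GAP_CHARS else -1
            for row in msa_rows
        ]
        present = [r for r in residues if r >= 0]
        types = set(present)
        if len(types) < 2:
            continue
        counts = {t: present.count(t) for t in types}
        r_types = len(types)
        for s, r in enumerate(residues):
            if r >= 0:
                w[s] += 1.0 / (r_types * counts[r])
    if w.sum() <= 0:
        w[:] = 1.0
    return w / w.sum()


def expected_distinct(n: float, background: np.ndarray) -> float:
    """E[number of distinct residue types | n independent background draws]."""
    p = np.asarray(background, dtype=float)
    return float((1.0 - np.power(1.0 - p, n)).sum())


def _invert_expected_distinct(mean_distinct: float, background: np.ndarray) -> float:
    if mean_distinct <= 1.0:
        return 1.0
    hi = 2.0
    while expected_distinct(hi, background) < mean_distinct:
        hi *= 2.0
        if hi > 1e7:
            return hi
    return float(
        brentq(lambda n: expected_distinct(n, background) - mean_distinct, 1.0, hi)
    )


def effective_observations(
    msa_rows: list[str], background: np.ndarray
) -> np.ndarray:
    """Per-column effective number of independent observations (>= 1).

    Columns are grouped into maximal blocks over which the same set of
    sequences participates (is non-gap); the mean distinct-residue count over
    the block is inverted through the expected-distinct curve, and the result
    is clamped to [1, number of participating sequences].  Gap-only columns
    get 1.0.
    """
    ncol = len(msa_rows[0])
    participation = [
        tuple(row[col] not in GAP_CHARS for row in msa_rows) for col in range(ncol)
    ]
    distinct = np.array(
        [len(set(_column_residues(msa_rows, col))) for col in range(ncol)], dtype=float
    )
    n_obs = np.ones(ncol)
    col = 0
    while col < ncol:
        block_end = col + 1
        while block_end < ncol and participation[block_end] == participation[col]:
            block_end += 1
        block = np.arange(col, block_end)
        informative = block[distinct[block] > 0]
        n_part = sum(participation[col])
        if len(informative) > 0 and n_part > 0:
            mean_distinct = float(distinct[informative].mean())
            est = _invert_expected_distinct(mean_distinct, background)
            n_obs[informative] = min(max(est, 1.0), float(n_part))
        col = block_end
    return n_obs


def build_profile(
    msa_rows: list[tuple[str, str]] | list[str],
    matrix: SubstitutionMatrix,
    profile_id: str = "profile",
    description: str = "",
) -> DomainProfile:
    """Build a DomainProfile from an aligned MSA.

    Frequencies are sequence-weighted residue tallies per column (gaps and
    ambiguous characters excluded, hence contributing zero counts);
    observation counts come from :func:`effective_observations`.
    """
    rows = [r[1] if isinstance(r, tuple) else r for r in msa_rows]
    if not rows:
        raise ValueError("empty MSA")
    ncol = len(rows[0])
    weights = sequence_weights(rows)
    freqs = np.zeros((ncol, 20))
    for col in range(ncol):
        for s, row in enumerate(rows):
            c = row[col]
            if c in GAP_CHARS:
                continue
            idx = Alphabet.index(c)
            if idx >= 0:
                freqs[col, idx] += weights[s]
        total = freqs[col].sum()
        if total > 0:
            freqs[col] /= total
    if not (freqs.sum(axis=1) > 0).any():
        raise ValueError(f"profile {profile_id}: MSA has no non-gap columns")
    n_obs = effective_observations(rows, matrix.background)
    return DomainProfile(
        id=profile_id, freqs=freqs, n_obs=n_obs, description=description
    )


# ---------------------------------------------------------------------------
# Library I/O: versioned structured text, one document per profile
# ---------------------------------------------------------------------------

class LibraryParseError(ValueError):
    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def write_library(library: ProfileLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# deltapssm domain profile library\n")
        fh.write(f"format_version: {FORMAT_VERSION}\n")
        for profile in library:
            fh.write(f">profile {profile.id}\n")
            fh.write(f"description: {profile.description}\n")
            sf = library.superfamily_of.get(profile.id, "")
            fh.write(f"superfamily: {sf if sf else '.'}\n")
            fh.write(f"length: {profile.length}\n")
            fh.write("n_obs: " + " ".join(_FREQ_FMT % v for v in profile.n_obs) + "\n")
            fh.write(f"consensus: {profile.consensus}\n")
            fh.write("freqs:\n")
            for row in profile.freqs:
                fh.write(" ".join(_FREQ_FMT % v for v in row) + "\n")
            fh.write("end\n")


def read_library(path: str | Path) -> ProfileLibrary:
    library = ProfileLibrary()
    state: dict = {}
    in_freqs = False

    def finish(lineno):
        if not state:
            return
        try:
            freqs = np.array(state["freqs"], dtype=float)
            profile = DomainProfile(
                id=state["id"],
                freqs=freqs,
                n_obs=np.array(state["n_obs"], dtype=float),
                consensus=state.get("consensus", ""),
                description=state.get("description", ""),
            )
        except (KeyError, ValueError) as exc:
            raise LibraryParseError(path, lineno, f"incomplete profile: {exc}")
        sf = state.get("superfamily", ".")
        library.add(profile, None if sf == "." else sf)
        if int(state.get("length", profile.length)) != profile.length:
            raise LibraryParseError(path, lineno, "declared length mismatch")
        state.clear()

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if stripped.startswith("format_version:"):
                version = stripped.split(":", 1)[1].strip()
                if int(version) != FORMAT_VERSION:
                    raise LibraryParseError(path, lineno, f"unsupported version {version}")
                continue
            if stripped.startswith(">profile"):
                parts = stripped.split(None, 1)
                if len(parts) < 2:
                    raise LibraryParseError(path, lineno, "profile header without id")
                state.clear()
                state["id"] = parts[1].strip()
                state["freqs"] = []
                in_freqs = False
                continue
            if not state:
                raise LibraryParseError(path, lineno, f"unexpected line {stripped!r}")
            if stripped == "end":
                finish(lineno)
                in_freqs = False
                continue
            if stripped == "freqs:":
                in_freqs = True
                continue
            if in_freqs:
                try:
                    state["freqs"].append([float(x) for x in stripped.split()])
                except ValueError:
                    raise LibraryParseError(path, lineno, "bad frequency row")
                continue
            if ":" not in stripped:
                raise LibraryParseError(path, lineno, f"unexpected line {stripped!r}")
            key, value = stripped.split(":", 1)
            key, value = key.strip(), value.strip()
            if key == "n_obs":
                try:
                    state["n_obs"] = [float(x) for x in value.split()]
                except ValueError:
                    raise LibraryParseError(path, lineno, "bad n_obs row")
            else:
                state[key] = value
    if state:
        raise LibraryParseError(path, lineno, "unterminated profile (missing 'end')")
    return library
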