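"""Seeded synthetic benchmarks with fold / superfamily / family structure.

The generator emulates the shape of a structure-classified benchmark
database (an ASTRAL/SCOP-like collection) and a curated domain-profile
library, so the whole search-and-evaluate pipeline can be exercised without
external data:

* each fold starts from an independent random ancestor drawn from the
  background composition; superfamily, family and leaf sequences descend
  from it with per-level divergence;
* substitutions follow the scoring model itself: at a site holding residue
  j, a substitution event replaces it with a draw from the conditional
  target distribution q(i|j) = q_ij / p_j, so conserved exchanges are
  preferred and the simulation is self-consistent with BLOSUM62;
* indels have geometrically distributed lengths (mean 2) and occur at a
  rate proportional to branch divergence; every residue carries a column
  identifier inherited from the ancestor, which yields exact reference
  alignments and gap-correct family MSAs for free;
* per family, additional held-out members feed the profile library and one
  held-out query is generated, neither of which enters the benchmark
  database.

Divergence is expressed as expected substitution *events* per site; because
conservative replacements often restore or retain the residue, realised
sequence identity is higher than exp(-divergence).  The default
configuration places cross-family identities within a superfamily in the
twilight range (roughly 15-25%), the regime where domain information should
matter most.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import json
import numpy as np
import yaml

from deltapssm.matrices import Alphabet, SubstitutionMatrix, default_matrix
from deltapssm.profiles import ProfileLibrary, build_profile, write_library
from deltapssm.evaluation import BenchmarkLabels, write_labels

__all__ = ["SimulationConfig", "SyntheticBenchmark", "simulate_benchmark",
           "simulate_profile_library", "write_fixture_set"]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic benchmark replicate."""

    seed: int = 0
    n_folds: int = 2
    superfamilies_per_fold: int = 2
    families_per_superfamily: int = 2
    seqs_per_family: int = 5
    seq_length: int = 120
    # expected substitution events per site on each branch level
    divergence_superfamily: float = 1.6
    divergence_family: float = 1.1
    divergence_leaf: float = 0.55
    # held-out material
    profile_members_per_family: int = 12
    divergence_profile_member: float = 1.0
    # indel events per site per unit divergence; geometric lengths, mean 2
    indel_rate: float = 0.01
    indel_mean_length: float = 2.0

    def validate(self) -> None:
        counts = (
            self.n_folds,
            self.superfamilies_per_fold,
            self.families_per_superfamily,
            self.seqs_per_family,
            self.seq_length,
            self.profile_members_per_family,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if min(
            self.divergence_superfamily,
            self.divergence_family,
            self.divergence_leaf,
            self.divergence_profile_member,
            self.indel_rate,
        ) < 0:
            raise ValueError("divergences and indel rate must be >= 0")
        if self.indel_mean_length < 1:
            raise ValueError("indel_mean_length must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


class _Evolver:
    """Substitution + indel machinery over (column-id, residue) sequences."""

    def __init__(self, matrix: SubstitutionMatrix, config: SimulationConfig,
                 rng: np.random.Generator):
        self.rng = rng
        self.config = config
        self.background = matrix.background
        cond = matrix.conditional_target()  # cond[:, j] = q(i | j)
        self.cond = cond / cond.sum(axis=0, keepdims=True)
        self._next_col = 0

    def fresh_columns(self, n: int) -> list[int]:
        cols = list(range(self._next_col, self._next_col + n))
        self._next_col += n
        return cols

    def root(self, length: int) -> list[tuple[int, int]]:
        residues = self.rng.choice(20, size=length, p=self.background)
        return list(zip(self.fresh_columns(length), residues.tolist()))

    def evolve(self, parent: list[tuple[int, int]], divergence: float):
        if divergence <= 0:
            return list(parent)
        seq = []
        p_sub = 1.0 - np.exp(-divergence)
        for col, res in parent:
            if self.rng.random() < p_sub:
                res = int(self.rng.choice(20, p=self.cond[:, res]))
            seq.append((col, res))
        n_events = self.rng.poisson(
            self.config.indel_rate * len(seq) * divergence
        )
        for _ in range(n_events):
            length = self.rng.geometric(1.0 / self.config.indel_mean_length)
            if self.rng.random() < 0.5 and len(seq) > length:  # deletion
                start = int(self.rng.integers(0, len(seq) - length + 1))
                del seq[start : start + length]
            else:  # insertion
                pos = int(self.rng.integers(0, len(seq) + 1))
                residues = self.rng.choice(20, size=length, p=self.background)
                inserted = list(zip(self.fresh_columns(length), residues.tolist()))
                seq[pos:pos] = inserted
        return seq


def _to_string(seq) -> str:
    return "".join(Alphabet.RESIDUES[res] for _, res in seq)


def _msa_column_order(ancestor_cols: list, member_col_lists: list) -> list:
    """Global MSA column order for sequences descending from one ancestor.

    The ancestor's columns form the backbone; each member's private
    (inserted) columns are slotted directly after the last ancestral column
    preceding them in that member (or before the backbone if none), which
    keeps every member's own column order monotone in the global order.
    Private columns of different members never co-occur, so their relative
    order within a slot is immaterial.
    """
    backbone = set(ancestor_cols)
    head: list = []
    slots: dict = {c: [] for c in ancestor_cols}
    for cols in member_col_lists:
        anchor = None
        for c in cols:
            if c in backbone:
                anchor = c
            elif anchor is None:
                head.append(c)
            else:
                slots[anchor].append(c)
    order = list(head)
    for c in ancestor_cols:
        order.append(c)
        order.extend(slots[c])
    return order


@dataclass
class SyntheticBenchmark:
    """A simulated database plus everything needed to evaluate searches."""

    config: SimulationConfig
    records: list  # database [(id, sequence string)]
    labels: BenchmarkLabels  # covers database + held-out queries
    columns: dict  # sequence id -> list of ancestral column ids
    holdout_queries: list  # [(id, sequence string)]
    profile_msas: dict = field(default_factory=dict)  # family -> [(id, row)]
    family_superfamily: dict = field(default_factory=dict)

    def reference_alignment(self, id_a: str, id_b: str) -> list:
        """True residue-pair alignment implied by shared ancestral columns."""
        cols_a, cols_b = self.columns[id_a], self.columns[id_b]
        pos_b = {c: i for i, c in enumerate(cols_b)}
        return [(i, pos_b[c]) for i, c in enumerate(cols_a) if c in pos_b]

    def total_positives(self, query_id: str) -> int:
        """Database sequences sharing the query's superfamily (self excluded)."""
        db_ids = {sid for sid, _ in self.records}
        sf = self.labels.superfamily[query_id]
        return sum(
            1
            for sid, _ in self.records
            if self.labels.superfamily[sid] == sf and sid != query_id
        )


def simulate_benchmark(config: SimulationConfig) -> SyntheticBenchmark:
    """Generate one seeded benchmark replicate (deterministic per config)."""
    config.validate()
    matrix = default_matrix()
    rng = np.random.default_rng(config.seed)
    ev = _Evolver(matrix, config, rng)

    records, columns = [], {}
    family, superfamily, fold = {}, {}, {}
    holdouts = []
    profile_msas = {}
    family_superfamily = {}

    def register(sid, seq, fam_id, sf_id, fold_id, into_db):
        string = _to_string(seq)
        columns[sid] = [c for c, _ in seq]
        family[sid], superfamily[sid], fold[sid] = fam_id, sf_id, fold_id
        if into_db:
            records.append((sid, string))
        return string

    for fi in range(config.n_folds):
        fold_id = f"f{fi + 1}"
        root = ev.root(config.seq_length)
        for si in range(config.superfamilies_per_fold):
            sf_id = f"{fold_id}.s{si + 1}"
            sf_anc = ev.evolve(root, config.divergence_superfamily)
            for mi in range(config.families_per_superfamily):
                fam_id = f"{sf_id}.m{mi + 1}"
                family_superfamily[fam_id] = sf_id
                fam_anc = ev.evolve(sf_anc, config.divergence_family)
                for k in range(config.seqs_per_family):
                    sid = f"d_{fam_id}_{k + 1:02d}".replace(".", "")
                    leaf = ev.evolve(fam_anc, config.divergence_leaf)
                    register(sid, leaf, fam_id, sf_id, fold_id, into_db=True)
                # held-out profile members -> family MSA via shared columns
                members = []
                for k in range(config.profile_members_per_family):
                    pid = f"p_{fam_id}_{k + 1:02d}".replace(".", "")
                    members.append(
                        (pid, ev.evolve(fam_anc, config.divergence_profile_member))
                    )
                order = _msa_column_order(
                    [c for c, _ in fam_anc], [[c for c, _ in seq] for _, seq in members]
                )
                index = {c: i for i, c in enumerate(order)}
                msa = []
                for pid, seq in members:
                    row = ["-"] * len(order)
                    for c, res in seq:
                        row[index[c]] = Alphabet.RESIDUES[res]
                    msa.append((pid, "".join(row)))
                profile_msas[fam_id] = msa
                # one held-out query per family
                qid = f"q_{fam_id}".replace(".", "")
                qseq = ev.evolve(fam_anc, config.divergence_leaf)
                holdouts.append(
                    (qid, register(qid, qseq, fam_id, sf_id, fold_id, into_db=False))
                )

    labels = BenchmarkLabels(family=family, superfamily=superfamily, fold=fold)
    return SyntheticBenchmark(
        config=config,
        records=records,
        labels=labels,
        columns=columns,
        holdout_queries=holdouts,
        profile_msas=profile_msas,
        family_superfamily=family_superfamily,
    )


def simulate_profile_library(
    benchmark: SyntheticBenchmark, matrix: SubstitutionMatrix | None = None
) -> ProfileLibrary:
    """One domain profile per family, built from the held-out family MSAs."""
    matrix = matrix or default_matrix()
    library = ProfileLibrary()
    for fam_id in sorted(benchmark.profile_msas):
        msa = benchmark.profile_msas[fam_id]
        if not msa:
            raise ValueError(f"family {fam_id} has no profile members")
        profile = build_profile(
            msa, matrix, profile_id=f"cd_{fam_id}".replace(".", ""),
            description=f"synthetic family profile for {fam_id}",
        )
        library.add(profile, superfamily=benchmark.family_superfamily[fam_id])
    return library


def write_fixture_set(benchmark: SyntheticBenchmark, out_dir: str | Path) -> dict:
    """Write db.fasta, queries.fasta, labels.tsv, refs.jsonl and lib.dpl."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def write_fasta(records, path):
        with open(path, "w") as fh:
            for sid, seq in records:
                fh.write(f">{sid}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")

    write_fasta(benchmark.records, out / "db.fasta")
    write_fasta(benchmark.holdout_queries, out / "queries.fasta")
    write_labels(benchmark.labels, out / "labels.tsv")
    library = simulate_profile_library(benchmark)
    write_library(library, out / "lib.dpl")
    # reference alignments of each held-out query to its true homologs
    with open(out / "refs.jsonl", "w") as fh:
        for qid, _ in benchmark.holdout_queries:
            sf = benchmark.labels.superfamily[qid]
            for sid, _ in benchmark.records:
                if benchmark.labels.superfamily[sid] != sf:
                    continue
                pairs = benchmark.reference_alignment(qid, sid)
                fh.write(
                    json.dumps(
                        {"query_id": qid, "subject_id": sid,
                         "aligned_pairs": pairs}
                    )
                    + "\n"
                )
    manifest = {
        "config": asdict(benchmark.config),
        "n_db": len(benchmark.records),
        "n_queries": len(benchmark.holdout_queries),
        "n_profiles": len(library),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
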