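# Methods

## Scoring system and statistics

All searches score in integer BLOSUM62 units with affine gap costs of
11 (open) + 1 per gapped residue, so a gap of length *k* costs 11 + *k*.
Background frequencies are the Robinson–Robinson amino-acid frequencies.
The matrix's target frequencies are reconstructed self-consistently from
its integer scores as q_ij = p_i p_j e^{λ_u s_ij}, where λ_u ≈ 0.3176 is
the unique positive root of Σ p_i p_j e^{λ s_ij} = 1 (solved by bracketed
bisection plus Newton polishing to 1e-9 relative). This choice has two
consequences we rely on: Σ q_ij = 1 holds to solver precision by
definition of λ_u, and a query-only PSSM (no domain hits, pure
pseudocounts) reproduces the matrix rows exactly after rounding, making
the plain-search fallback an algebraic identity rather than a separate
code path to trust. The gapped parameters for 11/1 gaps
(λ_g = 0.267, K_g = 0.041, H_g = 0.14) are stored as constants in the
packaged matrix file, following the convention of shipping
simulation-estimated gapped statistics with the matrix rather than
re-estimating them; E-values are K_g · m′ · n′ · e^{−λ_g S} with
BLAST-style effective lengths m′, n′ from the fixed-point length
adjustment ℓ = ln(K (m−ℓ)(n−Nℓ))/H.

Ambiguous residues (X, B, Z, J, U, O, \*) score as the background-weighted
average of the relevant score column and contribute zero observation
counts to profile and PSSM construction.

## Domain profiles

A profile column holds weighted observed residue frequencies and an
effective number of independent observations N_c ≥ 1. Sequence weights
are Henikoff position-based weights computed over columns with at least
two residue types. N_c is estimated by the distinct-residue-count
inversion: columns are grouped into maximal blocks sharing the same set of
participating sequences, the mean number of distinct residue types over
the block is computed, and that mean is mapped to an observation count by
inverting E[distinct | N] = Σ_i (1 − (1 − p_i)^N), clamped to
[1, number of participating sequences]. The inversion is a 1-d Brent root
find on the smooth, increasing expected-distinct curve. Several published
variants of this estimator exist; this one was chosen for being exactly
invertible and directly testable by Monte-Carlo simulation, and is
documented as a choice, not asserted as identical to any external tool's.

Profiles whose maximum N_c over all columns is below 6 are excluded from
the domain search before alignment: a profile built from near-identical
sequences carries almost no independent information and would produce a
narrowly focused PSSM. Query–profile alignments are kept only at
E ≤ 0.05. Both thresholds are exposed (`--min-obs`, `--evalue`).

## Domain search and PSSM construction

Each retained profile is converted to per-column integer scores using the
same pseudocount machinery as the final PSSM, with α = N_c − 1, and the
query is aligned to it by full affine-gap Smith–Waterman (Gotoh three-
matrix recursion, zero floor). Exhaustive dynamic programming over every
profile replaces word-seeded heuristics: at the scale this package
targets the exact optimum is affordable and simpler to verify. By default
one best alignment per profile is returned; `max_hsps > 1` yields
non-overlapping suboptimal alignments by iteratively masking the profile
columns already used.

Collapse follows the query-template rule set described in the README. Two
points were genuinely open and are resolved as follows:

* **Cross-profile column weight.** When several distinct profiles
  contribute to one query column, their observation weights are summed
  (α = Σ N_c + [query included] − 1). Summation treats distinct curated
  domain models as independent evidence; a normalising alternative (e.g.
  averaging) would make a column covered by many confident domains look no
  better observed than one covered by a single domain.
* **Query count under suppression.** Where the query residue is already
  represented among contributing profile columns, its unit observation is
  not tallied at all — it neither adds to f nor to α.

Pseudocount weight β defaults to 10 (`--pseudocount`), the classic
constant of the data-dependent pseudocount lineage. Scores are rounded to
the nearest integer, ties away from zero; a zero target frequency maps to
a floor score of (matrix minimum − 1). The real-valued PSSM is rescaled
by c = λ_PSSM/λ_u before rounding, where λ_PSSM solves the root equation
with uniform weights over PSSM rows; in the continuous domain this makes
the PSSM's λ equal λ_u exactly, so the matrix's gapped parameters apply.
Integer scores default to matrix units (scale 1) for reproducible small
integers; `--scale 32` mimics the up-scaled integer convention of
production BLAST. Coordinates are 0-based half-open internally and
1-based inclusive in reports.

## Evaluation machinery

Labels: same superfamily → true positive, different fold → false
positive, same fold but different superfamily → ignored, self-hits
removed. Pooled results are ranked by (E-value, −bit score, query id,
subject id) so ROC scores are deterministic under ties. ROC_n is
(1/(nT)) Σ_{i≤n} t_i with t_i the true positives ranked above the i-th
false positive; when fewer than n false positives exist the last t_i is
repeated (with none at all, every t_i is the list's true-positive count).
Standard errors use a seeded query-level bootstrap (1000 resamples by
default) — a documented substitute for closed-form ROC variance
estimators. Per-query ROC5 appends five synthetic false positives to each
list so the score is defined even for clean lists; queries with zero
positive relationships are excluded. Alignment sensitivity and precision
are plain set arithmetic over residue-index pairs, with references of
fewer than five pairs excluded by the caller; E-value calibration reports
the mean false-positive count per query at nominal E ≤ x and can solve
for the x crossing a target level (e.g. 0.3 FP/query).

## Synthetic benchmarks

The generator emulates the *shape* of a structure-classified benchmark: a
fold is an independent random root sequence (length 120 by default);
superfamily, family and leaf sequences descend from it with per-level
divergences of 1.6, 1.1 and 0.55 expected substitution events per site.
A substitution event redraws the residue from the matrix conditional
q(i|j) = q_ij/p_j, so conservative exchanges dominate and the simulation
is self-consistent with the scoring model rather than following an
explicit rate-matrix exponential. Indel events occur at 0.01 per site per
unit divergence with geometric lengths of mean 2; every residue carries an
ancestral column id, which yields exact reference alignments and
gap-correct family MSAs. With these defaults, cross-family pairs within a
superfamily sit at roughly 20% identity (twilight zone) and within-family
pairs near 50% — the regime where domain information is expected to
matter. Each family additionally yields 12 held-out profile members at
divergence 1.0 (diverse enough that every profile clears the
max N_c ≥ 6 filter) and one held-out query; neither enters the database.

What the simulation does **not** model: multi-domain architectures,
compositional bias and low-complexity regions, realistic indel hotspots,
structure-conserved cores versus loops, and curation noise in real domain
collections. Passing the synthetic benchmark therefore demonstrates the
correctness and internal consistency of the machinery and the qualitative
benefit of domain information under model-matched evolution — not
performance on real structural benchmarks.

## Problem sizes and determinism

The shipped experiment (tests and `scripts/acceptance.py`) uses 20
replicates of a 2 folds × 2 superfamilies × 2 families × 5 sequences
benchmark (40 database sequences, 8 queries, 8 profiles per replicate) and
pools ROC50 over all queries of a replicate; these sizes keep a full run
in the tens of seconds while leaving ~1600 positive relationships per
comparison. All randomness flows through a single seeded generator per
replicate; identical inputs produce byte-identical outputs, and the run
manifest records versions, seeds and thresholds.

## Known limitations

* Gapped (λ_g, K_g) are constants for the default gap costs; alternative
  gap costs would need their own parameters in the matrix file.
* No composition-based statistics and no low-complexity filtering; on real
  biased sequences nominal E-values will be less accurate than on the
  simulator's background-composition sequences.
* The RPS-style stage searches profiles exhaustively; it is exact but not
  engineered for libraries of tens of thousands of profiles.
* Iterative PSSM refinement over sequence hits is out of scope; the PSSM
  is built in a single pass from domain profiles only.
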