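"""Homology-detection and alignment-quality benchmarking.

The machinery mirrors standard SCOP-style evaluation practice:

* a query-subject pair is a true positive when the two sequences share a
  superfamily, a false positive when they lie in different folds, and
  unlabelled (ignored) when they share a fold but not a superfamily, since
  homology is then uncertain; self hits are removed;
* retrieval accuracy is the ROC_n score — the normalised area under the ROC
  curve up to the n-th false positive of the pooled, E-value-ranked result
  list — with standard errors from a seeded query-level bootstrap;
* per-query ROC_5 curves pad each query's list with five synthetic false
  positives at the end so the score is defined even for clean result lists;
* alignment quality is sensitivity |N∩S|/|S| and precision |N∩S|/|N| over
  residue-index pairs against a reference alignment;
* E-value calibration reports the mean number of false positives per query
  with nominal E-value <= x, as a step curve in x.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BenchmarkLabels",
    "RankedResults",
    "label_pair",
    "pool_results",
    "roc_n",
    "per_query_roc5",
    "alignment_quality",
    "bin_by_identity",
    "evalue_calibration",
    "calibration_threshold",
    "overlap_and_annotation_summary",
    "read_labels",
    "write_labels",
]

TP, FP, IGNORED, SELF = "TP", "FP", "ignored", "self"


@dataclass
class BenchmarkLabels:
    """family / superfamily / fold identifiers per sequence id.

    The hierarchy must be consistent: each family belongs to exactly one
    superfamily and each superfamily to exactly one fold.
    """

    family: dict
    superfamily: dict
    fold: dict

    def __post_init__(self):
        fam_sf: dict = {}
        sf_fold: dict = {}
        for sid in self.family:
            fam, sf, fold = self.family[sid], self.superfamily[sid], self.fold[sid]
            if fam_sf.setdefault(fam, sf) != sf:
                raise ValueError(f"family {fam} maps to multiple superfamilies")
            if sf_fold.setdefault(sf, fold) != fold:
                raise ValueError(f"superfamily {sf} maps to multiple folds")

    def __contains__(self, sid) -> bool:
        return sid in self.family

    def positives_of(self, query_id: str) -> set:
        """Benchmark ids sharing the query's superfamily (self excluded)."""
        sf = self.superfamily[query_id]
        return {
            sid
            for sid, s in self.superfamily.items()
            if s == sf and sid != query_id
        }


def label_pair(labels: BenchmarkLabels, query_id: str, subject_id: str) -> str:
    """Classify a query-subject pair as TP / FP / ignored / self."""
    for sid in (query_id, subject_id):
        if sid not in labels:
            raise KeyError(f"unknown sequence id {sid!r}")
    if query_id == subject_id:
        return SELF
    if labels.superfamily[query_id] == labels.superfamily[subject_id]:
        return TP
    if labels.fold[query_id] != labels.fold[subject_id]:
        return FP
    return IGNORED


@dataclass
class RankedResults:
    """Pooled labelled results sorted by (evalue, -bit score, ids)."""

    entries: list  # of (query_id, subject_id, evalue, label) with label TP/FP

    @property
    def n_tp(self) -> int:
        return sum(1 for e in self.entries if e[3] == TP)

    @property
    def n_fp(self) -> int:
        return sum(1 for e in self.entries if e[3] == FP)


def pool_results(hit_lists, labels: BenchmarkLabels) -> RankedResults:
    """Pool per-query hits, label them, drop self/ignored, sort by E-value.

    ``hit_lists`` is an iterable of SearchHit lists (one per query).  Ties in
    E-value are broken by bit score (descending) then (query id, subject id)
    so the ranking is deterministic.
    """
    rows = []
    for hits in hit_lists:
        for h in hits:
            lab = label_pair(labels, h.query_id, h.subject_id)
            if lab in (SELF, IGNORED):
                continue
            rows.append((h.evalue, -h.bit_score, h.query_id, h.subject_id, lab))
    rows.sort()
    return RankedResults(
        entries=[(q, s, ev, lab) for ev, _, q, s, lab in rows]
    )


def roc_n(
    results: RankedResults,
    n: int,
    total_positives: int,
    bootstrap: int = 0,
    seed: int = 0,
) -> tuple[float, float | None]:
    """ROC_n score of a pooled ranking, optionally with a bootstrap SE.

    score = (1 / (n T)) * sum_{i=1..n} t_i, where t_i is the number of true
    positives ranked above the i-th false positive and T is the number of
    positive relationships in the benchmark.  When the list holds fewer than
    n false positives the last t_i is repeated for the missing ranks (with
    zero false positives, every t_i is the total true-positive count).  The
    standard error, when requested, is the standard deviation of the score
    over ``bootstrap`` query-level resamples.
    """
    if n < 1 or total_positives < 1:
        raise ValueError("roc_n requires n >= 1 and total_positives >= 1")
    if not results.entries:
        raise ValueError("empty result list")
    score = _roc_n_score(results.entries, n, total_positives)
    se = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        queries = sorted({e[0] for e in results.entries})
        by_query = {q: [e for e in results.entries if e[0] == q] for q in queries}
        samples = np.empty(bootstrap)
        for b in range(bootstrap):
            chosen = rng.choice(len(queries), size=len(queries), replace=True)
            pooled = []
            for k in chosen:
                pooled.extend(by_query[queries[k]])
            pooled.sort(key=lambda e: (e[2], e[0], e[1]))
            samples[b] = _roc_n_score(pooled, n, total_positives)
        se = float(samples.std(ddof=1))
    return score, se


def _roc_n_score(entries, n: int, total_positives: int) -> float:
    t = 0
    total = 0
    fp_seen = 0
    last_t = 0
    for _, _, _, lab in entries:
        if lab == TP:
            t += 1
        elif lab == FP:
            fp_seen += 1
            last_t = t
            total += t
            if fp_seen == n:
                break
    if fp_seen < n:
        # repeat the final t_i for the missing false-positive ranks; with no
        # false positives at all, every t_i is the full true-positive count
        total += (n - fp_seen) * (last_t if fp_seen else t)
    return total / (n * total_positives)


def per_query_roc5(
    per_query_results: dict,
    total_positives: dict,
    thresholds=np.arange(0.1, 1.0, 0.1),
) -> tuple[dict, dict]:
    """Per-query ROC_5 scores plus the exceedance curve.

    ``per_query_results`` maps query id to its labelled entry list (pooled
    format, self/ignored removed); five synthetic false positives are
    appended to each list so up to five false-positive ranks always exist.
    Queries with zero positive relationships are excluded (with the
    rationale that a ROC score is undefined for them, as for
    singleton-superfamily queries).  Returns ({query: score}, {v: fraction
    of queries with score > v}).
    """
    scores = {}
    for qid, entries in per_query_results.items():
        t_q = total_positives.get(qid, 0)
        if t_q < 1:
            continue
        padded = list(entries) + [(qid, f"__fake_fp_{i}", np.inf, FP) for i in range(5)]
        scores[qid] = _roc_n_score(padded, 5, t_q)
    curve = {
        float(f"{v:.1f}"): (
            sum(1 for s in scores.values() if s > v) / len(scores) if scores else 0.0
        )
        for v in thresholds
    }
    return scores, curve


# ---------------------------------------------------------------------------
# Alignment quality
# ---------------------------------------------------------------------------

def alignment_quality(test_pairs, reference_pairs) -> tuple[float, float]:
    """Sensitivity |N∩S|/|S| and precision |N∩S|/|N| over residue pairs."""
    S = set(map(tuple, reference_pairs))
    if not S:
        raise ValueError("empty reference alignment")
    N = set(map(tuple, test_pairs))
    inter = len(N & S)
    return inter / len(S), (inter / len(N) if N else 0.0)


def bin_by_identity(records, bin_edges=np.arange(0.0, 0.35, 0.05)):
    """Average sensitivity/precision by reference sequence-identity bin.

    ``records`` is an iterable of (identity_fraction, sensitivity,
    precision).  Returns a DataFrame with bin midpoints and means.
    """
    df = pd.DataFrame(records, columns=["identity", "sensitivity", "precision"])
    df["bin"] = pd.cut(df["identity"], bins=bin_edges, include_lowest=True)
    grouped = df.groupby("bin", observed=True)[["sensitivity", "precision"]].mean()
    grouped["n"] = df.groupby("bin", observed=True).size()
    return grouped.reset_index()


# ---------------------------------------------------------------------------
# Nominal E-value calibration
# ---------------------------------------------------------------------------

def evalue_calibration(per_query_results: dict, grid) -> np.ndarray:
    """Mean number of false positives per query with nominal E <= x.

    Returns an array aligned with ``grid``; the curve is a monotone
    non-decreasing step function of x.
    """
    grid = np.asarray(grid, dtype=float)
    n_queries = len(per_query_results)
    if n_queries == 0:
        raise ValueError("no queries")
    fp_evalues = np.array(
        sorted(
            ev
            for entries in per_query_results.values()
            for _, _, ev, lab in entries
            if lab == FP
        )
    )
    counts = np.searchsorted(fp_evalues, grid, side="right")
    return counts / n_queries


def calibration_threshold(
    per_query_results: dict, target_mean_fp: float
) -> float:
    """Largest nominal E-value x with mean FP count per query <= target.

    This is the threshold-matching construction used to put methods with
    differently calibrated E-values on an equal false-positive footing.
    """
    fp_evalues = sorted(
        ev
        for entries in per_query_results.values()
        for _, _, ev, lab in entries
        if lab == FP
    )
    n_queries = len(per_query_results)
    allowed = int(np.floor(target_mean_fp * n_queries))
    if allowed >= len(fp_evalues):
        return float("inf")
    # crossing point: any x below the (allowed+1)-th FP E-value qualifies
    return float(np.nextafter(fp_evalues[allowed], -np.inf))


# ---------------------------------------------------------------------------
# TP set overlap and domain-annotation categories
# ---------------------------------------------------------------------------

def overlap_and_annotation_summary(
    results_per_method: dict,
    labels: BenchmarkLabels,
    thresholds: dict,
    annotation: dict | None = None,
    profile_superfamily: dict | None = None,
) -> dict:
    """TP-set overlaps between methods and domain-annotation categories.

    ``results_per_method`` maps method name to its pooled labelled entries;
    ``thresholds`` maps method name to its E-value cutoff.  ``annotation``
    maps sequence id to a set of associated profile ids (the E <= 0.01
    association convention); ``profile_superfamily`` maps profile id to its
    profile-collection superfamily.  For each method the TP pairs below its
    threshold are categorised: shared profile when the two annotation sets
    intersect, shared profile superfamily when the mapped superfamily sets
    intersect, different superfamilies when both have superfamily
    annotations but none in common, and unannotated when either sequence has
    no associated profile.  The same- and different-superfamily fractions
    need not sum to one because not every profile carries a superfamily.
    """
    tp_sets = {}
    for method, entries in results_per_method.items():
        cutoff = thresholds[method]
        tp_sets[method] = {
            (q, s) for q, s, ev, lab in entries if lab == TP and ev <= cutoff
        }
    methods = sorted(tp_sets)
    out: dict = {"tp_counts": {m: len(tp_sets[m]) for m in methods}, "overlap": {}}
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            out["overlap"][f"{a}&{b}"] = len(tp_sets[a] & tp_sets[b])
    if len(methods) >= 3:
        inter = set.intersection(*(tp_sets[m] for m in methods))
        out["overlap"]["&".join(methods)] = len(inter)
    union = set.union(*tp_sets.values()) if tp_sets else set()
    out["union"] = len(union)

    if annotation is not None:
        cats = {}
        sf_of = profile_superfamily or {}
        for method in methods:
            counts = {
                "same_profile": 0,
                "same_superfamily": 0,
                "different_superfamilies": 0,
                "unannotated": 0,
            }
            pairs = tp_sets[method]
            for q, s in pairs:
                aq = set(annotation.get(q, ()))
                as_ = set(annotation.get(s, ()))
                if not aq or not as_:
                    counts["unannotated"] += 1
                    continue
                if aq & as_:
                    counts["same_profile"] += 1
                sq = {sf_of[p] for p in aq if p in sf_of}
                ss = {sf_of[p] for p in as_ if p in sf_of}
                if sq & ss:
                    counts["same_superfamily"] += 1
                elif sq and ss:
                    counts["different_superfamilies"] += 1
            total = max(len(pairs), 1)
            cats[method] = {k: v / total for k, v in counts.items()}
            cats[method]["n_tp"] = len(pairs)
        out["annotation_categories"] = cats
    return out


# ---------------------------------------------------------------------------
# Label table I/O (TSV: id, family, superfamily, fold)
# ---------------------------------------------------------------------------

def read_labels(path: str | Path) -> BenchmarkLabels:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "family", "superfamily", "fold"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: label table needs columns {sorted(required)}")
    return BenchmarkLabels(
        family=dict(zip(df["id"], df["family"])),
        superfamily=dict(zip(df["id"], df["superfamily"])),
        fold=dict(zip(df["id"], df["fold"])),
    )


def write_labels(labels: BenchmarkLabels, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tfamily\tsuperfamily\tfold\n")
        for sid in sorted(labels.family):
            fh.write(
                f"{sid}\t{labels.family[sid]}\t{labels.superfamily[sid]}"
                f"\t{labels.fold[sid]}\n"
            )
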