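"""ROC machinery, alignment quality, calibration and overlap summaries."""

import numpy as np
import pytest

from deltapssm.evaluation import (
    FP,
    TP,
    BenchmarkLabels,
    RankedResults,
    alignment_quality,
    bin_by_identity,
    calibration_threshold,
    evalue_calibration,
    label_pair,
    overlap_and_annotation_summary,
    per_query_roc5,
    roc_n,
)
from oracles import roc_n_enumeration


@pytest.fixture()
def labels():
    ids = {
        "a1": ("fam1", "sfA", "foldX"),
        "a2": ("fam1", "sfA", "foldX"),
        "a3": ("fam2", "sfA", "foldX"),
        "b1": ("fam3", "sfB", "foldX"),
        "c1": ("fam4", "sfC", "foldY"),
    }
    return BenchmarkLabels(
        family={k: v[0] for k, v in ids.items()},
        superfamily={k: v[1] for k, v in ids.items()},
        fold={k: v[2] for k, v in ids.items()},
    )


class TestLabelPair:
    def test_same_superfamily_is_tp(self, labels):
        assert label_pair(labels, "a1", "a3") == TP

    def test_different_fold_is_fp(self, labels):
        assert label_pair(labels, "a1", "c1") == FP

    def test_same_fold_different_superfamily_ignored(self, labels):
        assert label_pair(labels, "a1", "b1") == "ignored"

    def test_self_hit(self, labels):
        assert label_pair(labels, "a1", "a1") == "self"

    def test_unknown_id_rejected(self, labels):
        with pytest.raises(KeyError):
            label_pair(labels, "a1", "zz")

    def test_inconsistent_hierarchy_rejected(self):
        with pytest.raises(ValueError):
            BenchmarkLabels(
                family={"x": "f1", "y": "f1"},
                superfamily={"x": "s1", "y": "s2"},
                fold={"x": "F", "y": "F"},
            )


def ranked(labels_seq):
    return RankedResults(
        entries=[("q", f"s{i}", float(i), lab) for i, lab in enumerate(labels_seq)]
    )


class TestRocN:
    def test_perfect_ranking_scores_one(self):
        results = ranked([TP] * 4 + [FP] * 6)
        score, _ = roc_n(results, 3, 4)
        assert score == 1.0

    def test_worst_ranking_scores_zero(self):
        results = ranked([FP] * 3 + [TP] * 4)
        score, _ = roc_n(results, 3, 4)
        assert score == 0.0

    def test_hand_listed_example(self):
        # ranking: TP FP TP TP FP TP FP FP TP FP ; n=3, T=4
        seq = [TP, FP, TP, TP, FP, TP, FP, FP, TP]
        score, _ = roc_n(ranked(seq), 3, 4)
        # t_1=1, t_2=3, t_3=4 -> 8/12
        assert score == pytest.approx(8 / 12)

    def test_matches_enumeration_oracle_on_random_lists(self, rng):
        for _ in range(60):
            seq = list(rng.choice([TP, FP], size=rng.integers(1, 60)))
            n = int(rng.integers(1, 10))
            t_total = max(seq.count(TP), 1)
            score, _ = roc_n(ranked(seq), n, t_total)
            assert score == pytest.approx(roc_n_enumeration(seq, n, t_total))

    def test_fewer_fps_than_n_repeats_last_value(self):
        seq = [TP, FP, TP]
        score, _ = roc_n(ranked(seq), 5, 2)
        # t_1 = 1; missing ranks repeat 1 -> 5*1 / (5*2)
        assert score == pytest.approx(0.5)

    def test_no_fps_uses_total_tp_count(self):
        seq = [TP, TP, TP]
        score, _ = roc_n(ranked(seq), 5, 3)
        assert score == 1.0

    def test_bootstrap_se_deterministic(self):
        # queries differ in ranking quality so resampling has real variance
        patterns = [[TP, TP, FP, FP], [FP, TP, FP, TP], [TP, FP, TP, FP]]
        entries = []
        for q in range(6):
            for i, lab in enumerate(patterns[q % 3]):
                entries.append((f"q{q}", f"s{i}", float(i + q * 0.1), lab))
        results = RankedResults(entries)
        _, se1 = roc_n(results, 3, 12, bootstrap=100, seed=5)
        _, se2 = roc_n(results, 3, 12, bootstrap=100, seed=5)
        assert se1 == se2
        assert se1 > 0

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            roc_n(RankedResults([]), 3, 4)


class TestPerQueryRoc5:
    def test_only_tps_score_one(self):
        pq = {"q": [("q", f"s{i}", 1e-5, TP) for i in range(5)]}
        scores, _ = per_query_roc5(pq, {"q": 5})
        assert scores["q"] == 1.0

    def test_empty_list_scores_zero_via_padding(self):
        scores, curve = per_query_roc5({"q": []}, {"q": 3})
        assert scores["q"] == 0.0

    def test_toy_list_matches_padded_enumeration(self):
        seq = [TP, FP, TP, TP, FP, TP, FP]
        pq = {"q": [("q", f"s{i}", float(i), lab) for i, lab in enumerate(seq)]}
        scores, _ = per_query_roc5(pq, {"q": 4})
        padded = seq + [FP] * 5
        assert scores["q"] == pytest.approx(roc_n_enumeration(padded, 5, 4))

    def test_zero_positive_queries_excluded(self):
        scores, _ = per_query_roc5({"q": [("q", "s", 1.0, FP)]}, {"q": 0})
        assert scores == {}

    def test_exceedance_curve_fractions(self):
        pq = {
            "hi": [("hi", f"s{i}", 1e-9, TP) for i in range(3)],
            "lo": [("lo", "s0", 1e-3, FP)],
        }
        _, curve = per_query_roc5(pq, {"hi": 3, "lo": 2})
        assert curve[0.5] == pytest.approx(0.5)  # only "hi" exceeds 0.5


class TestAlignmentQuality:
    def test_identical_alignments(self):
        pairs = [(i, i + 2) for i in range(10)]
        assert alignment_quality(pairs, pairs) == (1.0, 1.0)

    def test_disjoint_alignments(self):
        n = [(0, 0), (1, 1)]
        s = [(5, 5), (6, 6)]
        assert alignment_quality(n, s) == (0.0, 0.0)

    def test_direct_arithmetic(self):
        s = [(i, i) for i in range(10)]
        n = [(i, i) for i in range(6)] + [(20 + i, i) for i in range(2)]
        sens, prec = alignment_quality(n, s)
        assert sens == pytest.approx(6 / 10)
        assert prec == pytest.approx(6 / 8)

    def test_swapping_swaps_the_two_measures(self, rng):
        for _ in range(30):
            n = {(int(a), int(b)) for a, b in rng.integers(0, 12, size=(10, 2))}
            s = {(int(a), int(b)) for a, b in rng.integers(0, 12, size=(8, 2))}
            if not n or not s:
                continue
            sens, prec = alignment_quality(list(n), list(s))
            sens2, prec2 = alignment_quality(list(s), list(n))
            assert sens == pytest.approx(prec2)
            assert prec == pytest.approx(sens2)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            alignment_quality([(0, 0)], [])

    def test_identity_binning_means(self):
        records = [(0.12, 1.0, 0.5), (0.13, 0.0, 0.5), (0.28, 0.4, 0.9)]
        table = bin_by_identity(records)
        first = table[table["n"] == 2].iloc[0]
        assert first["sensitivity"] == pytest.approx(0.5)
        assert first["precision"] == pytest.approx(0.5)


class TestCalibration:
    def _pq(self):
        return {
            "q1": [("q1", "a", 0.002, FP), ("q1", "b", 0.5, FP)],
            "q2": [("q2", "c", 0.05, FP)],
            "q3": [("q3", "d", 1e-4, TP)],
        }

    def test_monotone_and_counts(self):
        grid = [1e-5, 1e-3, 0.01, 0.1, 1.0, 10.0]
        curve = evalue_calibration(self._pq(), grid)
        assert list(curve) == sorted(curve)
        # direct counting: FP E-values are 0.002, 0.05, 0.5 over 3 queries
        assert curve[0] == 0.0
        assert curve[2] == pytest.approx(1 / 3)
        assert curve[-1] == pytest.approx(1.0)

    def test_extremes(self):
        curve = evalue_calibration(self._pq(), [1e-9, 1e9])
        assert curve[0] == 0.0
        assert curve[-1] == pytest.approx(3 / 3)

    def test_threshold_solving(self):
        # mean FP <= 0.3 over 3 queries allows 0 FPs; the crossing sits just
        # below the smallest FP E-value (0.002)
        x = calibration_threshold(self._pq(), 0.3)
        curve = evalue_calibration(self._pq(), [x])
        assert curve[0] <= 0.3
        eps = np.nextafter(0.002, 1.0)
        assert evalue_calibration(self._pq(), [eps])[0] > 0.3

    def test_threshold_solving_recovers_mid_level(self):
        x = calibration_threshold(self._pq(), 0.4)  # one FP allowed
        assert 0.002 <= x < 0.05
        assert evalue_calibration(self._pq(), [x])[0] <= 0.4


class TestOverlap:
    def _entries(self, pairs, label=TP, ev=1e-5):
        return [(q, s, ev, label) for q, s in pairs]

    def test_disjoint_methods_have_empty_intersections(self, labels):
        res = {
            "m1": self._entries([("a1", "a2")]),
            "m2": self._entries([("a1", "a3")]),
        }
        out = overlap_and_annotation_summary(res, labels, {"m1": 0.01, "m2": 0.01})
        assert out["overlap"]["m1&m2"] == 0
        assert out["union"] == 2

    def test_identical_sets_intersect_fully(self, labels):
        pairs = [("a1", "a2"), ("a1", "a3")]
        res = {"m1": self._entries(pairs), "m2": self._entries(pairs)}
        out = overlap_and_annotation_summary(res, labels, {"m1": 1, "m2": 1})
        assert out["overlap"]["m1&m2"] == 2 == out["tp_counts"]["m1"]

    def test_three_methods_match_set_algebra(self, labels, rng):
        pool = [("a1", "a2"), ("a1", "a3"), ("a2", "a3"), ("a2", "a1"), ("a3", "a1"), ("a3", "a2")]
        sets = {}
        res = {}
        for m in ("m1", "m2", "m3"):
            chosen = [pool[i] for i in rng.choice(6, size=4, replace=False)]
            sets[m] = set(chosen)
            res[m] = self._entries(chosen)
        out = overlap_and_annotation_summary(
            res, labels, {m: 0.01 for m in res}
        )
        assert out["overlap"]["m1&m2"] == len(sets["m1"] & sets["m2"])
        assert out["overlap"]["m1&m2&m3"] == len(
            sets["m1"] & sets["m2"] & sets["m3"]
        )
        assert out["union"] == len(sets["m1"] | sets["m2"] | sets["m3"])

    def test_annotation_categories(self, labels):
        res = {"m": self._entries([("a1", "a2"), ("a1", "a3"), ("a2", "a3")])}
        annotation = {
            "a1": {"cd1"},
            "a2": {"cd1", "cd2"},
            "a3": {"cd3"},
        }
        sf = {"cd1": "S1", "cd2": "S2", "cd3": "S1"}
        out = overlap_and_annotation_summary(
            res, labels, {"m": 0.01}, annotation=annotation, profile_superfamily=sf
        )
        cats = out["annotation_categories"]["m"]
        # (a1,a2): share cd1 and superfamily S1; (a1,a3): different profiles,
        # same superfamily S1; (a2,a3): no shared profile, shared S1 via cd1/cd3
        assert cats["same_profile"] == pytest.approx(1 / 3)
        assert cats["same_superfamily"] == pytest.approx(1.0)
        assert cats["different_superfamilies"] == 0.0
        assert cats["unannotated"] == 0.0

    def test_thresholds_gate_tp_sets(self, labels):
        res = {"m": [("a1", "a2", 0.5, TP), ("a1", "a3", 1e-6, TP)]}
        out = overlap_and_annotation_summary(res, labels, {"m": 0.01})
        assert out["tp_counts"]["m"] == 1
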