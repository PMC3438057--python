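"""Collapse rules, pseudocount mixing, score derivation and PSSM scaling."""

import numpy as np
import pytest

from deltapssm.domain_search import ProfileHit
from deltapssm.matrices import Alphabet
from deltapssm.profiles import DomainProfile, ProfileLibrary
from deltapssm.pssm import (
    build_pssm,
    collapse,
    observed_frequencies,
    pssm_scores,
    pssm_ungapped_lambda,
    read_pssm,
    scale_pssm,
    target_frequencies,
    write_pssm,
)

AA = list(Alphabet.RESIDUES)


def point_profile(sequence, n_obs, pid):
    freqs = np.zeros((len(sequence), 20))
    for i, aa in enumerate(sequence):
        freqs[i, Alphabet.index(aa)] = 1.0
    return DomainProfile(id=pid, freqs=freqs, n_obs=np.full(len(sequence), n_obs))


def mixed_profile(length, rows, n_obs, pid):
    freqs = np.zeros((length, 20))
    for i, spec in enumerate(rows):
        for aa, w in spec.items():
            freqs[i, Alphabet.index(aa)] = w
    return DomainProfile(id=pid, freqs=freqs, n_obs=np.asarray(n_obs, dtype=float))


def hit(pid, pairs, evalue=1e-6, raw=100, qid="q"):
    qs = [p[0] for p in pairs]
    ps = [p[1] for p in pairs]
    return ProfileHit(
        query_id=qid,
        profile_id=pid,
        raw_score=raw,
        bit_score=50.0,
        evalue=evalue,
        aligned_pairs=pairs,
        query_range=(min(qs), max(qs) + 1),
        profile_range=(min(ps), max(ps) + 1),
    )


class TestCollapse:
    def test_no_hits_gives_query_only_columns(self):
        cols = collapse("ACD", [], ProfileLibrary())
        assert len(cols) == 3
        for c in cols:
            assert c.contributions == []
            assert c.query_included

    def test_query_suppressed_where_residue_represented(self, matrix):
        # profile column gives the query residue A weight 0.3 at position 0
        prof = mixed_profile(1, [{"A": 0.3, "V": 0.7}], [4.0], "p")
        lib = ProfileLibrary()
        lib.add(prof)
        cols = collapse("AC", [hit("p", [(0, 0)])], lib)
        assert not cols[0].query_included  # A already represented
        assert cols[1].query_included  # untouched position keeps the query

    def test_query_kept_when_residue_absent_from_contributions(self, matrix):
        prof = mixed_profile(1, [{"V": 1.0}], [4.0], "p")
        lib = ProfileLibrary()
        lib.add(prof)
        cols = collapse("A", [hit("p", [(0, 0)])], lib)
        assert cols[0].query_included

    def test_lowest_evalue_wins_per_column_within_profile(self):
        prof = mixed_profile(
            2, [{"V": 1.0}, {"W": 1.0}], [3.0, 5.0], "p"
        )
        lib = ProfileLibrary()
        lib.add(prof)
        h_good = hit("p", [(0, 0)], evalue=1e-8)
        h_bad = hit("p", [(0, 1)], evalue=1e-3)
        cols = collapse("A", [h_bad, h_good], lib)
        assert len(cols[0].contributions) == 1
        assert cols[0].contributions[0].profile_col == 0
        assert cols[0].contributions[0].evalue == 1e-8

    def test_gap_only_profile_columns_ignored(self):
        freqs = np.zeros((2, 20))
        freqs[1, Alphabet.index("V")] = 1.0
        prof = DomainProfile(id="p", freqs=freqs, n_obs=np.array([1.0, 4.0]))
        lib = ProfileLibrary()
        lib.add(prof)
        cols = collapse("AC", [hit("p", [(0, 0), (1, 1)])], lib)
        assert cols[0].contributions == []  # column 0 carried no residues
        assert len(cols[1].contributions) == 1

    def test_unknown_profile_rejected(self):
        with pytest.raises(KeyError):
            collapse("A", [hit("ghost", [(0, 0)])], ProfileLibrary())


class TestObservedFrequencies:
    def test_query_only_point_mass(self):
        cols = collapse("A", [], ProfileLibrary())
        f, alpha = observed_frequencies(cols[0])
        assert alpha == 0.0
        assert f[Alphabet.index("A")] == 1.0

    def test_single_contribution_normalisation(self):
        prof = mixed_profile(1, [{"V": 0.5, "L": 0.5}], [9.0], "p")
        lib = ProfileLibrary()
        lib.add(prof)
        cols = collapse("V", [hit("p", [(0, 0)])], lib)
        f, alpha = observed_frequencies(cols[0])
        assert not cols[0].query_included
        assert alpha == pytest.approx(8.0)
        assert f[Alphabet.index("V")] == pytest.approx(0.5)
        assert f[Alphabet.index("L")] == pytest.approx(0.5)

    def test_two_contributions_plus_query(self):
        pa = mixed_profile(1, [{"V": 1.0}], [6.0], "pa")
        pb = mixed_profile(1, [{"L": 1.0}], [3.0], "pb")
        lib = ProfileLibrary()
        lib.add(pa)
        lib.add(pb)
        cols = collapse("A", [hit("pa", [(0, 0)]), hit("pb", [(0, 0)])], lib)
        f, alpha = observed_frequencies(cols[0])
        assert cols[0].query_included
        assert alpha == pytest.approx(9.0)  # 6 + 3 + 1 (query) - 1
        expected = np.zeros(20)
        expected[Alphabet.index("V")] = 6.0
        expected[Alphabet.index("L")] = 3.0
        expected[Alphabet.index("A")] = 1.0
        assert f == pytest.approx(expected / 10.0)


class TestTargetFrequencies:
    def test_alpha_zero_gives_pure_prior(self, matrix, rng):
        f = rng.dirichlet(np.ones(20))
        g = matrix.target_freqs @ (f / matrix.background)
        g = g / g.sum()
        q = target_frequencies(f, 0.0, matrix)
        assert q == pytest.approx(g, rel=1e-12)

    def test_alpha_large_returns_observed(self, matrix, rng):
        f = rng.dirichlet(np.ones(20))
        q = target_frequencies(f, 1e9, matrix)
        assert np.abs(q - f).max() < 1e-6

    def test_rows_sum_to_one(self, matrix, rng):
        for _ in range(50):
            f = rng.dirichlet(np.full(20, rng.uniform(0.2, 5.0)))
            q = target_frequencies(f, rng.uniform(0, 50), matrix)
            assert q.sum() == pytest.approx(1.0, abs=1e-9)

    def test_background_input_recovers_background(self, matrix):
        q = target_frequencies(matrix.background, 5.0, matrix)
        # g(p) has the matrix's marginal composition, which is close to p by
        # construction of the target frequencies
        assert np.abs(q - matrix.background).max() < 5e-3


class TestScores:
    def test_background_targets_score_zero(self, matrix):
        q_rows = np.tile(matrix.background, (4, 1))
        scores, _ = pssm_scores(q_rows, matrix.background, matrix.ungapped_lambda)
        assert np.array_equal(scores, np.zeros((4, 20), dtype=np.int64))

    def test_log_additivity(self, matrix):
        q = np.tile(matrix.background, (1, 1)) * 2.0
        _, real1 = pssm_scores(
            np.tile(matrix.background, (1, 1)),
            matrix.background,
            matrix.ungapped_lambda,
        )
        _, real2 = pssm_scores(q, matrix.background, matrix.ungapped_lambda)
        shift = np.log(2.0) / matrix.ungapped_lambda
        assert real2 == pytest.approx(real1 + shift, rel=1e-12)

    def test_zero_target_maps_to_floor(self, matrix):
        q = np.tile(matrix.background, (1, 1))
        q[0, 3] = 0.0
        scores, _ = pssm_scores(
            q, matrix.background, matrix.ungapped_lambda,
            floor_score=matrix.min_score - 1,
        )
        assert scores[0, 3] == matrix.min_score - 1


class TestScalePssm:
    def test_matrix_rows_are_a_fixed_point(self, matrix, make_sequence):
        query = make_sequence(60)
        rows = matrix.score_rows_for(Alphabet.encode(query)).astype(float)
        scaled, c = scale_pssm(rows, matrix)
        assert c == pytest.approx(1.0, abs=0.05)
        assert np.array_equal(scaled, rows.astype(np.int64))

    def test_rescaled_lambda_matches_matrix(self, matrix, make_sequence):
        # build a 10-position PSSM, rescale, and verify with the lambda oracle
        query = make_sequence(10)
        pssm = build_pssm(query, None, matrix, hits=[])
        rows = matrix.score_rows_for(Alphabet.encode(query)).astype(float)
        lam_before = pssm_ungapped_lambda(rows, matrix.background)
        c = lam_before / matrix.ungapped_lambda
        lam_after = pssm_ungapped_lambda(rows * c, matrix.background)
        assert lam_after == pytest.approx(matrix.ungapped_lambda, rel=1e-4)

    def test_doubling_scores_halves_lambda(self, matrix, make_sequence):
        query = make_sequence(30)
        rows = matrix.score_rows_for(Alphabet.encode(query)).astype(float)
        lam = pssm_ungapped_lambda(rows, matrix.background)
        lam2 = pssm_ungapped_lambda(2 * rows, matrix.background)
        assert lam2 == pytest.approx(lam / 2.0, rel=1e-9)


class TestBuildPssm:
    def test_query_only_reproduces_matrix_rows(self, matrix, make_sequence):
        query = make_sequence(70)
        pssm = build_pssm(query, None, matrix, hits=[])
        expected = matrix.score_rows_for(Alphabet.encode(query))
        assert np.array_equal(pssm.scores, expected)
        assert pssm.metadata["fallback"]

    def test_target_rows_sum_to_one(self, matrix, make_sequence):
        query = make_sequence(40)
        prof = point_profile(query[5:25], 8.0, "p")
        lib = ProfileLibrary()
        lib.add(prof)
        pssm = build_pssm(query, lib, matrix)
        assert pssm.target_freqs.sum(axis=1) == pytest.approx(
            np.ones(40), abs=1e-9
        )

    def test_covered_columns_gain_alpha(self, matrix, make_sequence):
        query = make_sequence(40)
        prof = point_profile(query[5:25], 8.0, "p")
        lib = ProfileLibrary()
        lib.add(prof)
        pssm = build_pssm(query, lib, matrix)
        assert (pssm.alpha[5:25] > 0).all()
        assert (pssm.alpha[:5] == 0).all()
        assert (pssm.alpha[25:] == 0).all()

    def test_hit_order_invariance(self, matrix, make_sequence):
        query = make_sequence(30)
        pa = point_profile(query[0:20], 7.0, "pa")
        pb = point_profile(query[8:28], 8.0, "pb")
        lib = ProfileLibrary()
        lib.add(pa)
        lib.add(pb)
        from deltapssm.domain_search import search_domains

        hits = search_domains(query, lib, matrix, inclusion_evalue=10.0)
        fwd = build_pssm(query, lib, matrix, hits=hits)
        rev = build_pssm(query, lib, matrix, hits=list(reversed(hits)))
        assert np.array_equal(fwd.scores, rev.scores)
        np.testing.assert_allclose(fwd.target_freqs, rev.target_freqs)

    def test_uncovered_columns_unaffected_by_extra_profile(
        self, matrix, make_sequence
    ):
        query = make_sequence(36)
        pa = point_profile(query[0:12], 7.0, "pa")
        pb = point_profile(query[20:34], 8.0, "pb")
        lib_a = ProfileLibrary()
        lib_a.add(pa)
        lib_both = ProfileLibrary()
        lib_both.add(pa)
        lib_both.add(pb)
        p_one = build_pssm(query, lib_a, matrix)
        p_two = build_pssm(query, lib_both, matrix)
        # columns never touched by pb keep identical target frequencies
        np.testing.assert_allclose(
            p_one.target_freqs[0:12], p_two.target_freqs[0:12], rtol=1e-12
        )

    def test_determinism_and_round_trip(self, matrix, make_sequence, tmp_path):
        query = make_sequence(30)
        prof = point_profile(query[3:27], 8.0, "p")
        lib = ProfileLibrary()
        lib.add(prof)
        a = build_pssm(query, lib, matrix)
        b = build_pssm(query, lib, matrix)
        assert np.array_equal(a.scores, b.scores)
        p1, p2 = tmp_path / "a.pssm", tmp_path / "b.pssm"
        write_pssm(a, p1)
        write_pssm(b, p2)
        assert p1.read_bytes() == p2.read_bytes()
        again = read_pssm(p1)
        assert np.array_equal(again.scores, a.scores)
        assert again.query == a.query
        assert again.gapped_lambda == a.gapped_lambda
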