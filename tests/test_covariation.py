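"""Co-variation scoring: weighting, MI+APC, mfDCA, ranking and filtering."""

import numpy as np
import pytest

from mitonet.covariation import (
    CovaryingPair,
    EmptyIntersectionError,
    ScoreMatrix,
    combine_methods,
    concatenate,
    effective_sequences,
    filter_inter,
    filter_intra,
    mfdca,
    mi_apc,
    mutual_information,
    read_icoms_matrix,
    read_score_matrix,
    sequence_weights,
    top_pairs,
    write_score_matrix,
)
from mitonet.simulate import simulate_alignment
from tests.conftest import make_alignment


class TestConcatenate:
    def test_widths_and_segments(self):
        a = make_alignment(["MKLV", "MKLA", "MKIV"], name="MT-ND1")
        b = make_alignment(["ACDEFG", "ACDEFA", "ACDEFC"], name="MT-CO1")
        cat = concatenate([a, b])
        assert cat.n_columns == 10
        assert [(s.protein, s.start, s.end) for s in cat.segments] == [
            ("MT-ND1", 0, 4),
            ("MT-CO1", 4, 10),
        ]
        assert cat.alignment.sequences[0] == "MKLVACDEFG"

    def test_only_shared_species_retained(self):
        a = make_alignment(
            ["MKLV", "MKLA", "MKIV"],
            species=["Homo sapiens", "Bos taurus", "Mus musculus"],
            name="MT-ND1",
        )
        b = make_alignment(
            ["ACDE", "ACDA"],
            species=["Homo sapiens", "Bos taurus"],
            name="MT-CO1",
        )
        cat = concatenate([a, b])
        assert cat.alignment.species == ("Homo sapiens", "Bos taurus")

    def test_duplicate_species_resolved_by_distance_to_human(self):
        a = make_alignment(
            ["MKLV", "MQIA", "MKLA"],  # second Bos row is closer to human
            species=["Homo sapiens", "Bos taurus", "Bos taurus"],
            name="MT-ND1",
        )
        b = make_alignment(
            ["ACDE", "ACDA"],
            species=["Homo sapiens", "Bos taurus"],
            name="MT-CO1",
        )
        cat = concatenate([a, b])
        assert cat.alignment.sequences[1] == "MKLAACDA"

    def test_no_shared_species_raises(self):
        a = make_alignment(["MKLV", "MKLA"], species=["Homo sapiens", "Bos taurus"])
        b = make_alignment(["ACDE", "ACDA"], species=["Pan troglodytes", "Mus musculus"])
        with pytest.raises(EmptyIntersectionError):
            concatenate([a, b])


class TestSequenceWeights:
    def test_full_redundancy(self):
        aln = make_alignment(["MKLVA"] * 4)
        w = sequence_weights(aln)
        assert np.allclose(w, 0.25)
        assert effective_sequences(w) == pytest.approx(1.0)

    def test_all_distinct_below_threshold(self):
        aln = make_alignment(["AAAAA", "CCCCC", "DDDDD"])
        assert np.allclose(sequence_weights(aln, 0.8), 1.0)

    def test_two_identical_plus_one_distinct(self):
        aln = make_alignment(["MKLVA", "MKLVA", "ACDEF"])
        w = sequence_weights(aln, 0.8)
        assert np.allclose(w, [0.5, 0.5, 1.0])
        assert effective_sequences(w) == pytest.approx(2.0)


class TestMutualInformation:
    def test_perfectly_coupled_binary_columns_give_one_bit(self):
        # 2x2 table with p(A,C) = p(C,A) = 1/2: MI = 1 bit
        seqs = ["AC"] * 4 + ["CA"] * 4
        aln = make_alignment(seqs)
        mi = mutual_information(aln, pseudocount=0.0, weights=np.ones(8))
        assert mi[0, 1] == pytest.approx(1.0)

    def test_independent_columns_approach_zero(self):
        rng = np.random.default_rng(5)
        n = 4000
        seqs = [
            "".join(rng.choice(["A", "C"], size=2)) for _ in range(n)
        ]
        aln = make_alignment(seqs)
        mi = mutual_information(aln, pseudocount=0.0, weights=np.ones(n))
        assert mi[0, 1] < 5e-3

    def test_matrix_symmetry(self):
        aln, _ = simulate_alignment(30, 12, 0.4, seed=2)
        m = mi_apc(aln)
        assert np.allclose(m.scores, m.scores.T)

    def test_single_column_rejected(self):
        aln = make_alignment(["A", "C"])
        with pytest.raises(ValueError):
            mutual_information(aln)


class TestMfdca:
    def test_iid_columns_have_near_zero_di(self):
        # background DI is finite-sample noise and decays with alignment
        # depth; at M_eff ~ 1500 it sits well below planted-pair scores (~1)
        aln, _ = simulate_alignment(1500, 20, 0.6, seed=3)
        m = mfdca(aln)
        off = m.scores[np.triu_indices(20, k=1)]
        assert off.max() < 0.05

    def test_planted_pair_attains_maximal_di(self):
        aln, truth = simulate_alignment(
            200, 30, 0.5, coupled_pairs=[(4, 21, 0.95)], seed=4
        )
        m = mfdca(aln)
        i, j = np.unravel_index(np.argmax(m.scores), m.scores.shape)
        assert {int(i), int(j)} == {4, 21}

    def test_di_symmetric_and_nonnegative(self):
        aln, _ = simulate_alignment(80, 15, 0.4, seed=5)
        m = mfdca(aln)
        assert np.allclose(m.scores, m.scores.T)
        assert (m.scores >= -1e-12).all()


class TestPermutationEquivariance:
    def test_row_order_leaves_scores_unchanged(self):
        aln, _ = simulate_alignment(60, 10, 0.4, seed=6)
        perm = np.random.default_rng(0).permutation(aln.n_records)
        # keep the human row identifiable after permutation
        shuffled = make_alignment(
            [aln.sequences[i] for i in perm],
            species=[aln.species[i] for i in perm],
            reference_index=int(np.where(perm == 0)[0][0]),
        )
        w1 = sequence_weights(aln)
        w2 = sequence_weights(shuffled)
        assert np.allclose(
            mi_apc(aln, weights=w1).scores, mi_apc(shuffled, weights=w2).scores
        )
        assert np.allclose(
            mfdca(aln, weights=w1).scores, mfdca(shuffled, weights=w2).scores
        )


def _matrix(scores, columns, method="MI_APC"):
    return ScoreMatrix(method=method, scores=np.array(scores, float), columns=columns)


class TestTopPairs:
    COLS = (("P1", 1), ("P1", 2), ("P2", 1))

    def test_score_order(self):
        m = _matrix(
            [[0, 5, 3], [5, 0, 1], [3, 1, 0]], self.COLS
        )
        pairs = top_pairs(m, 2)
        assert [(p.score, p.protein_a, p.position_a, p.protein_b, p.position_b)
                for p in pairs] == [
            (5.0, "P1", 1, "P1", 2),
            (3.0, "P1", 1, "P2", 1),
        ]

    def test_n_exceeding_pair_count_returns_all(self):
        m = _matrix([[0, 5, 3], [5, 0, 1], [3, 1, 0]], self.COLS)
        assert len(top_pairs(m, 500)) == 3

    def test_tie_break_is_positional(self):
        m = _matrix([[0, 2, 2], [2, 0, 2], [2, 2, 0]], self.COLS)
        pairs = top_pairs(m, 3)
        assert [(p.protein_a, p.position_a, p.protein_b, p.position_b)
                for p in pairs] == [
            ("P1", 1, "P1", 2),
            ("P1", 1, "P2", 1),
            ("P1", 2, "P2", 1),
        ]

    def test_human_gapped_columns_excluded(self):
        cols = (("P1", 1), ("P1", None), ("P2", 1))
        m = _matrix([[0, 9, 3], [9, 0, 9], [3, 9, 0]], cols)
        pairs = top_pairs(m, 10)
        assert len(pairs) == 1
        assert pairs[0].score == 3.0

    def test_nested_selection(self):
        rng = np.random.default_rng(7)
        s = rng.normal(size=(6, 6))
        s = s + s.T
        np.fill_diagonal(s, 0)
        cols = tuple(("P1", k + 1) for k in range(6))
        m = _matrix(s, cols)
        smaller = {(p.position_a, p.position_b) for p in top_pairs(m, 4)}
        larger = {(p.position_a, p.position_b) for p in top_pairs(m, 9)}
        assert smaller <= larger


def _pair(pa, ia, pb, ib, method="MI_APC", score=1.0):
    return CovaryingPair(pa, ia, pb, ib, method, score)


class TestFilters:
    def test_inter_keeps_cross_protein_only(self):
        pairs = [_pair("MT-ND1", 3, "MT-CO1", 7), _pair("MT-CO1", 1, "MT-CO1", 9)]
        kept = filter_inter(pairs)
        assert len(kept) == 1 and kept[0].klass == "inter"

    def test_intra_excludes_concatenated_protein(self):
        pairs = [
            _pair("MT-ND1", 3, "MT-ND1", 9),  # inside the concatenated protein
            _pair("MT-ND1", 3, "MT-CO1", 7),  # crosses into it
            _pair("MT-CO1", 1, "MT-CO1", 9),  # fully in the partner
        ]
        kept = filter_intra(pairs, concat_protein="MT-ND1")
        assert [(p.protein_a, p.position_a, p.position_b) for p in kept] == [
            ("MT-CO1", 1, 9)
        ]
        assert kept[0].klass == "intra"

    def test_classes_are_disjoint(self):
        pairs = [
            _pair("MT-ND1", 1, "MT-ND1", 2),
            _pair("MT-ND1", 1, "MT-CO1", 2),
            _pair("MT-CO1", 1, "MT-CO1", 2),
        ]
        inter_keys = {p.key for p in filter_inter(pairs)}
        intra_keys = {p.key for p in filter_intra(pairs)}
        assert not inter_keys & intra_keys

    def test_empty_inputs(self):
        assert filter_inter([]) == []
        assert filter_intra([]) == []


class TestCombineMethods:
    def test_disjoint_lists(self):
        a = [_pair("P1", i, "P2", i) for i in (1, 2, 3)]
        b = [_pair("P1", i, "P2", i, method="mfDCA") for i in (4, 5)]
        union, common = combine_methods(a, b)
        assert len(union) == 5 and common == []

    def test_identical_lists(self):
        a = [_pair("P1", i, "P2", i) for i in (1, 2, 3, 4)]
        b = [_pair("P1", i, "P2", i, method="mfDCA") for i in (1, 2, 3, 4)]
        union, common = combine_methods(a, b)
        assert len(union) == 8 and len(common) == 4

    def test_shared_pair_found_regardless_of_order(self):
        a = [_pair("P1", 1, "P2", 9)]
        b = [_pair("P2", 9, "P1", 1, method="mfDCA")]
        _, common = combine_methods(a, b)
        assert len(common) == 1


class TestOnDiskFormats:
    def test_score_matrix_round_trip(self, tmp_path):
        aln, _ = simulate_alignment(30, 8, 0.4, seed=8)
        m = mi_apc(aln)
        path = tmp_path / "scores.tsv"
        write_score_matrix(m, path)
        again = read_score_matrix(path)
        assert again.method == m.method
        assert again.columns == m.columns
        assert np.allclose(again.scores, m.scores)

    def test_icoms_dialect_adapter(self, tmp_path):
        path = tmp_path / "icoms.txt"
        path.write_text(
            "# raw scores\n"
            "MT-ND1/1\tMT-ND1/2\tMT-CO1/1\n"
            "MT-ND1/1\t0.0\t1.5\t0.2\n"
            "MT-ND1/2\t1.5\t0.0\t2.5\n"
            "MT-CO1/1\t0.2\t2.5\t0.0\n"
        )
        m = read_icoms_matrix(path, method="cMI")
        assert m.columns == (("MT-ND1", 1), ("MT-ND1", 2), ("MT-CO1", 1))
        pairs = top_pairs(m, 1)
        assert pairs[0].score == 2.5
        assert (pairs[0].protein_a, pairs[0].protein_b) == ("MT-ND1", "MT-CO1")
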