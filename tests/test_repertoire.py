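"""Repertoire analytics: filtering, diversity, overlap, alignment, clustering."""

import math

import numpy as np
import pandas as pd
import pytest

from cx3score import (
    DistanceMatrix,
    Repertoire,
    RepertoireSpec,
    clonality,
    filter_productive,
    gini_from_lorenz,
    gini_index,
    lorenz_curve,
    morisita_overlap,
    pam10_align,
    seq_distance,
    shared_exact_clonotypes,
    simulate_repertoire,
    top_n_aa,
    upgma_dendrogram,
)
from cx3score.errors import ValidationError
from cx3score.pam import load_pam10

from conftest import align_enumeration, gini_pairwise


def make_rep(counts, aa=None, status=None):
    n = len(counts)
    df = pd.DataFrame({
        "nucleotide": [f"NT{i:03d}" for i in range(n)],
        "amino_acid": aa if aa is not None else [f"CASS{chr(65 + i % 26)}F" for i in range(n)],
        "count": counts,
        "v_gene": "TRBV01", "j_gene": "TRBJ1-1",
        "status": status if status is not None else "In",
    })
    return Repertoire.from_counts(df)


class TestProductiveFiltering:
    def test_all_productive_unchanged(self):
        rep = make_rep([4, 3, 3])
        out = filter_productive(rep)
        assert out.clonotypes["frequency"].tolist() == rep.clonotypes["frequency"].tolist()

    def test_renormalisation_doubles_frequencies(self):
        rep = make_rep([5, 5, 5, 5], status=["In", "In", "Out", "Out"])
        out = filter_productive(rep)
        assert out.n_clonotypes == 2
        assert np.allclose(out.frequencies, [0.5, 0.5])

    def test_five_row_mixed_file(self, toy_repertoire):
        out = filter_productive(toy_repertoire)
        assert out.n_clonotypes == 4
        assert np.allclose(out.frequencies, np.array([40, 10, 30, 15]) / 95)

    def test_empty_after_filter_is_error(self):
        rep = make_rep([2, 2], status=["Out", "Out"])
        with pytest.raises(ValidationError):
            filter_productive(rep)


class TestClonality:
    def test_uniform_is_zero(self):
        for r in (2, 5, 50):
            assert clonality(make_rep([3] * r)) == pytest.approx(0.0, abs=1e-12)

    def test_entropy_oracle_half_quarter_quarter(self):
        rep = make_rep([2, 1, 1])
        h = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        assert clonality(rep) == pytest.approx(1 - h / math.log(3), abs=1e-12)
        assert clonality(rep) == pytest.approx(0.0536, abs=1e-4)

    def test_near_monoclonal_approaches_one(self):
        assert clonality(make_rep([999, 1])) > 0.98

    def test_single_clonotype_undefined(self):
        assert math.isnan(clonality(make_rep([10])))

    def test_increases_when_mass_moves_to_largest_clone(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            counts = np.sort(rng.integers(1, 60, size=6))
            if counts[0] < 2:
                counts[0] += 2
            before = clonality(make_rep(counts.tolist()))
            shifted = counts.copy()
            shifted[0] -= 1
            shifted[-1] += 1
            after = clonality(make_rep(shifted.tolist()))
            assert after > before


class TestMorisita:
    def test_identical_repertoires_give_one(self):
        rep = make_rep([10, 5, 3])
        assert morisita_overlap(rep, rep) == pytest.approx(1.0)

    def test_disjoint_sets_give_zero(self):
        a = make_rep([5, 5])
        b = make_rep([5, 5])
        b.clonotypes["nucleotide"] = ["OTHER1", "OTHER2"]
        assert morisita_overlap(a, b) == pytest.approx(0.0)

    def test_hand_formula_example(self):
        a = make_rep([1, 1])                       # x: 0.5, y: 0.5
        b = make_rep([2])                          # x: 1.0
        b.clonotypes["nucleotide"] = [a.clonotypes["nucleotide"].iloc[0]]
        assert morisita_overlap(a, b) == pytest.approx(2 * 0.5 / 1.5)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            a = make_rep(rng.integers(1, 50, size=8).tolist())
            b = make_rep(rng.integers(1, 50, size=8).tolist())
            keep = rng.integers(0, 8)
            b.clonotypes.loc[b.clonotypes.index[keep:], "nucleotide"] = [
                f"ALT{i}" for i in range(8 - keep)
            ]
            ab = morisita_overlap(a, b)
            ba = morisita_overlap(b, a)
            assert ab == pytest.approx(ba, abs=1e-12)
            assert 0.0 <= ab <= 1.0

    def test_classic_variant_on_identical_counts(self):
        # the count-based index with Simpson correction can slightly exceed 1
        rep = make_rep([30, 20, 10])
        assert morisita_overlap(rep, rep, variant="classic") == pytest.approx(1.0, abs=0.05)


class TestGiniLorenz:
    def test_uniform_is_zero(self):
        assert gini_index([0.25] * 4) == pytest.approx(0.0, abs=1e-12)

    def test_pairwise_oracle_example(self):
        assert gini_index([0.1, 0.2, 0.3, 0.4]) == pytest.approx(0.25, abs=1e-12)
        assert gini_pairwise([0.1, 0.2, 0.3, 0.4]) == pytest.approx(0.25, abs=1e-12)

    def test_dominant_clone_limit(self):
        r = 50
        f = np.full(r, 1e-9)
        f[-1] = 1.0 - f[:-1].sum()
        assert gini_index(f) == pytest.approx((r - 1) / r, abs=1e-6)

    def test_lorenz_examples(self):
        pts = lorenz_curve([0.1, 0.2, 0.3, 0.4])
        assert pts[0].tolist() == [0.0, 0.0]
        assert pts[-1].tolist() == [1.0, 1.0]
        assert pts[2].tolist() == pytest.approx([0.5, 0.3])
        diffs = np.diff(pts[:, 1])
        assert (np.diff(diffs) >= -1e-12).all()  # convex

    def test_gini_equals_one_minus_twice_lorenz_area(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            f = rng.dirichlet(np.full(rng.integers(2, 40), 0.4))
            g = gini_index(f)
            assert g == pytest.approx(gini_from_lorenz(lorenz_curve(f)), abs=1e-9)
            assert g == pytest.approx(gini_pairwise(f), abs=1e-9)


class TestTopN:
    def test_fewer_sequences_than_n_returns_all_with_flag(self):
        rep = make_rep([3, 2, 1], aa=["CASSAF", "CASSBF", "CASSCF"])
        top, short = top_n_aa(rep, n=100)
        assert len(top) == 3 and short

    def test_same_aa_from_two_nt_clonotypes_aggregates(self):
        rep = make_rep([3, 1], aa=["CASSAF", "CASSAF"])
        top, _ = top_n_aa(rep, n=10)
        assert top == [("CASSAF", pytest.approx(1.0))]

    def test_top_100_matches_independent_sort(self):
        rep = simulate_repertoire(RepertoireSpec(n_clones=500, total_templates=20000, seed=12))
        top, short = top_n_aa(rep, n=100)
        assert not short and len(top) == 100
        agg = rep.clonotypes.groupby("amino_acid")["frequency"].sum()
        expected = agg.sort_values(ascending=False).iloc[:100].sum()
        assert sum(f for _, f in top) == pytest.approx(expected, abs=1e-12)
        freqs = [f for _, f in top]
        assert freqs == sorted(freqs, reverse=True)


class TestSharedClonotypes:
    def test_disjoint_and_identical(self):
        a = [("CASSAF", 0.6), ("CASSBF", 0.4)]
        b = [("CASSCF", 1.0)]
        assert shared_exact_clonotypes(a, b)[0] == 0
        assert shared_exact_clonotypes(a, a)[0] == 2

    def test_single_shared_dominant_sequence(self):
        a = [("CASSLVGNQDTQYF", 0.3), ("CASSPRLGDNYAEQFF", 0.2)]
        b = [("CASSLVGNQDTQYF", 0.25), ("CASSPGYAEQFF", 0.1)]
        count, shared = shared_exact_clonotypes(a, b)
        assert count == 1 and shared == ["CASSLVGNQDTQYF"]


class TestAlignment:
    def test_self_score_is_diagonal_sum(self):
        pam = load_pam10()
        seq = "CASSLVGNQDTQYF"
        assert pam10_align(seq, seq) == pytest.approx(sum(pam[c, c] for c in seq))

    def test_empty_or_unknown_residue_rejected(self):
        with pytest.raises(ValidationError):
            pam10_align("", "CASSF")
        with pytest.raises(ValidationError, match="position 2"):
            pam10_align("CAXSF", "CASSF")

    def test_matches_exhaustive_enumeration_on_short_pairs(self):
        pam = load_pam10()
        rng = np.random.default_rng(19)
        alphabet = "ARNDC"
        for _ in range(150):
            a = "".join(rng.choice(list(alphabet), rng.integers(1, 5)))
            b = "".join(rng.choice(list(alphabet), rng.integers(1, 5)))
            assert pam10_align(a, b) == pytest.approx(
                align_enumeration(a, b, pam, 30.0), abs=1e-9
            )

    def test_distance_zero_at_identity_symmetric(self):
        assert seq_distance("CASSF", "CASSF") == 0.0
        d1 = seq_distance("CASSLVGF", "CASTRAPF")
        d2 = seq_distance("CASTRAPF", "CASSLVGF")
        assert d1 == pytest.approx(d2) and d1 > 0

    def test_dissimilar_pair_distance_can_exceed_one(self):
        # maximally mismatched short sequences have negative cross-scores
        assert seq_distance("WWWW", "DDDD") > 1.0


class TestUPGMA:
    def test_unique_closest_pair_merges_first_at_half_distance(self):
        dm = DistanceMatrix(labels=["A", "B", "C"],
                            matrix=np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0.0]]))
        tree = upgma_dendrogram(dm)
        heights = tree.merge_heights()
        assert heights[0] == pytest.approx(0.5)
        assert heights[-1] == pytest.approx(5.0)

    def test_ultrametric_input_reproduced_exactly(self):
        # four leaves with tree distances 2, 4, 8
        d = np.array([
            [0, 2, 8, 8],
            [2, 0, 8, 8],
            [8, 8, 0, 4],
            [8, 8, 4, 0.0],
        ])
        dm = DistanceMatrix(labels=list("ABCD"), matrix=d)
        coph = upgma_dendrogram(dm).cophenetic()
        assert np.allclose(coph.matrix, d)

    def test_permutation_invariant_topology(self):
        rng = np.random.default_rng(27)
        n = 7
        base = rng.uniform(0.5, 3.0, size=(n, n))
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0.0)
        labels = [f"L{i}" for i in range(n)]
        ref = upgma_dendrogram(DistanceMatrix(labels=labels, matrix=d)).cophenetic()
        perm = rng.permutation(n)
        shuffled = upgma_dendrogram(
            DistanceMatrix(labels=[labels[i] for i in perm], matrix=d[np.ix_(perm, perm)])
        ).cophenetic()
        order = [shuffled.labels.index(lab) for lab in ref.labels]
        assert np.allclose(shuffled.matrix[np.ix_(order, order)], ref.matrix)

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(29)
        for _ in range(10):
            n = rng.integers(3, 10)
            base = rng.uniform(0.1, 5.0, size=(n, n))
            d = (base + base.T) / 2
            np.fill_diagonal(d, 0.0)
            tree = upgma_dendrogram(
                DistanceMatrix(labels=[str(i) for i in range(n)], matrix=d)
            )
            h = tree.merge_heights()
            assert h == sorted(h)

    def test_newick_round_trip_leaf_set(self):
        dm = DistanceMatrix(labels=["A", "B", "C"],
                            matrix=np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0.0]]))
        newick = upgma_dendrogram(dm).to_newick()
        assert newick.endswith(";")
        for lab in "ABC":
            assert lab in newick
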