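"""Trees, PCoA trait extraction, signal indices, UPGMA and NJ."""

import numpy as np
import pandas as pd
import pytest

from segdist.distance import DistanceMatrix
from segdist.phylo import (
    PhyloTree,
    abouheif_cmean,
    blomberg_k,
    morans_i,
    neighbor_joining,
    pagel_lambda,
    pcoa_axis1,
    signal_report,
    upgma,
)
from segdist.synthetic import pure_birth_tree, simulate_bm_trait


BALANCED4 = "((A:1,B:1):2,(C:1,D:1):2);"


class TestPhyloTree:
    def test_newick_round_trip(self):
        t = PhyloTree.from_newick("((A:1,B:1):2,C:3);")
        t2 = PhyloTree.from_newick(t.to_newick())
        assert t2.tip_labels == ["A", "B", "C"]
        assert np.allclose(t2.tip_depths().to_numpy(), [3.0, 3.0, 3.0])

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PhyloTree.from_newick("((A:1,A:1):2,C:3);")

    def test_ultrametric_check(self):
        assert PhyloTree.from_newick("((A:1,B:1):2,C:3);").is_ultrametric()
        assert not PhyloTree.from_newick("((A:1,B:2):2,C:3);").is_ultrametric()

    def test_underscored_labels_preserved(self):
        t = PhyloTree.from_newick("((Mus_musculus:1,Rattus_norvegicus:1):2,Homo_sapiens:3);")
        assert "Mus_musculus" in t.tip_labels
        assert "Mus_musculus" in t.to_newick()

    def test_file_round_trip_preserves_lengths(self, tmp_path):
        t = PhyloTree.from_newick("((A:1.23456789,B:1.23456789):2.5,C:3.73456789);")
        path = tmp_path / "t.nwk"
        t.write(path)
        t2 = PhyloTree.read(path)
        assert np.allclose(t2.tip_depths().to_numpy(),
                           t.tip_depths().to_numpy(), atol=1e-9)

    def test_vcv_and_patristic(self):
        t = PhyloTree.from_newick(BALANCED4)
        V = t.vcv(["A", "B", "C", "D"])
        assert V[0, 0] == pytest.approx(3.0)
        assert V[0, 1] == pytest.approx(2.0)
        assert V[0, 2] == pytest.approx(0.0)
        P = t.patristic_matrix(["A", "B", "C", "D"])
        assert P[0, 1] == pytest.approx(2.0)
        assert P[0, 2] == pytest.approx(6.0)

    def test_abouheif_proximity_known_values(self):
        t = PhyloTree.from_newick(BALANCED4)
        A = t.abouheif_proximity(["A", "B", "C", "D"])
        assert A[0, 1] == pytest.approx(1 / 2)   # via one internal node (dd=2)
        assert A[0, 2] == pytest.approx(1 / 8)   # through the root: 2*2*2


class TestPcoa:
    def test_two_point_special_case(self):
        m = DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        coords = pcoa_axis1(m)
        assert coords["a"] == pytest.approx(0.5)
        assert coords["b"] == pytest.approx(-0.5)

    def test_recovers_points_on_a_line(self):
        x = np.array([0.0, 1.0, 3.0, 7.0, 9.0])
        v = np.abs(x[:, None] - x[None, :])
        m = DistanceMatrix(tuple("abcde"), v)
        coords = pcoa_axis1(m).to_numpy()
        rec = np.abs(coords[:, None] - coords[None, :])
        assert np.allclose(rec, v, atol=1e-8)

    def test_sign_convention_first_taxon_non_negative(self):
        x = np.array([5.0, 1.0, 0.0])
        m = DistanceMatrix(tuple("abc"), np.abs(x[:, None] - x[None, :]))
        assert pcoa_axis1(m)["a"] >= 0


class TestMoransI:
    def test_permutation_null_expectation(self, tree32):
        rng = np.random.default_rng(0)
        x = rng.normal(size=32)
        labels = tree32.tip_labels
        P = tree32.patristic_matrix(labels)
        with np.errstate(divide="ignore"):
            W = 1.0 / P
        np.fill_diagonal(W, 0.0)
        W /= W.sum(axis=1, keepdims=True)
        stats = []
        for _ in range(3000):
            z = rng.permutation(x)
            z = z - z.mean()
            stats.append(z @ W @ z / (z @ z))
        assert np.mean(stats) == pytest.approx(-1 / 31, abs=0.004)

    def test_clade_indicator_trait_is_significant(self):
        t = PhyloTree.from_newick(
            "((A:1,B:1,C:1,D:1):3,(E:1,F:1,G:1,H:1):3);")
        trait = {lab: (1.0 if lab in "ABCD" else 0.0) for lab in t.tip_labels}
        # jitter to avoid a constant within-clade trait
        rng = np.random.default_rng(1)
        trait = {k: v + rng.normal(0, 0.05) for k, v in trait.items()}
        res = morans_i(trait, t, n_perm=999, seed=0)
        assert res.estimate > 0 and res.p_value <= 0.05

    def test_p_values_reproducible_and_in_grid(self, tree32):
        x = simulate_bm_trait(tree32, 1.0, seed=4)
        r1 = morans_i(x, tree32, n_perm=99, seed=7)
        r2 = morans_i(x, tree32, n_perm=99, seed=7)
        assert r1.p_value == r2.p_value
        assert r1.p_value in [k / 100 for k in range(1, 101)]


class TestAbouheifCmean:
    def test_row_normalised_weights(self, tree32):
        from segdist.phylo import _row_standardise
        W = _row_standardise(tree32.abouheif_proximity())
        assert np.allclose(W.sum(axis=1), 1.0)

    def test_bm_traits_show_signal(self, tree32):
        hits = 0
        for rep in range(20):
            x = simulate_bm_trait(tree32, 1.0, seed=rep)
            if abouheif_cmean(x, tree32, n_perm=199, seed=rep).p_value <= 0.05:
                hits += 1
        assert hits >= 14

    def test_affine_invariance(self, tree32):
        x = simulate_bm_trait(tree32, 1.0, seed=9)
        a = abouheif_cmean(x, tree32, n_perm=99, seed=1)
        b = abouheif_cmean(3.5 * x - 11.0, tree32, n_perm=99, seed=1)
        assert a.estimate == pytest.approx(b.estimate)
        assert a.p_value == b.p_value


class TestBlombergK:
    def test_affine_invariance(self, tree32):
        x = simulate_bm_trait(tree32, 1.0, seed=2)
        a = blomberg_k(x, tree32, n_perm=99, seed=1)
        b = blomberg_k(-2.0 * x + 7.0, tree32, n_perm=99, seed=1)
        assert a.k == pytest.approx(b.k)
        assert a.k_star == pytest.approx(b.k_star)

    def test_shuffled_traits_lose_signal(self, tree32):
        rng = np.random.default_rng(3)
        low_k, ns = 0, 0
        for rep in range(20):
            x = simulate_bm_trait(tree32, 1.0, seed=100 + rep).to_numpy()
            rng.shuffle(x)
            res = blomberg_k(dict(zip(tree32.tip_labels, x)), tree32,
                             n_perm=199, seed=rep)
            low_k += res.k < 1
            ns += res.p_k > 0.05
        assert low_k >= 18 and ns >= 15


class TestPagelLambda:
    def test_lambda_zero_transform_kills_covariances(self, tree32):
        from segdist.phylo import _lambda_cov
        V = tree32.vcv()
        C0 = _lambda_cov(V, 0.0)
        assert np.allclose(C0, np.diag(np.diag(V)))
        assert np.allclose(np.diag(C0), np.diag(V))

    def test_matches_reference_implementation_values(self, tree32):
        """Frozen cross-check: lambda-hat agrees with phytools::phylosig on
        the same tree and traits (values computed once with R 4.3)."""
        rng = np.random.default_rng(9)
        X = rng.normal(size=(3, 32))
        expected = [0.0, 0.0, 0.1056]  # phytools lambda-hat (<=1e-4 shown as 0)
        for row, exp in zip(X, expected):
            res = pagel_lambda(dict(zip(tree32.tip_labels, row)), tree32)
            assert res.lambda_hat == pytest.approx(exp, abs=2e-3)

    def test_shuffled_traits_estimate_near_zero(self, tree128):
        rng = np.random.default_rng(5)
        lams = []
        for rep in range(30):
            x = simulate_bm_trait(tree128, 1.0, seed=rep).to_numpy()
            rng.shuffle(x)
            lams.append(pagel_lambda(dict(zip(tree128.tip_labels, x)),
                                     tree128).lambda_hat)
        assert np.mean(lams) <= 0.2

    def test_bm_trait_significant(self, tree32):
        x = simulate_bm_trait(tree32, 1.0, seed=0)
        res = pagel_lambda(x, tree32)
        assert res.lambda_hat > 0.7 and res.p_value < 0.05


class TestSignalReport:
    def test_report_shapes_and_determinism(self, tree32):
        x = simulate_bm_trait(tree32, 1.0, seed=1)
        r1 = signal_report(x, tree32, n_perm=99, seed=3, trait_name="ax1")
        r2 = signal_report(x, tree32, n_perm=99, seed=3, trait_name="ax1")
        assert r1.to_dict() == r2.to_dict()
        d = r1.to_dict()
        assert set(d) >= {"cmean", "morans_i", "blomberg_k", "blomberg_k_star",
                          "pagel_lambda"}
        assert all(0 < d[k]["p"] <= 1 for k in
                   ("cmean", "morans_i", "blomberg_k", "blomberg_k_star"))
        row = r1.to_tsv_row()
        assert row.startswith("ax1\t") and len(row.split("\t")) == 6


class TestUpgma:
    def test_hand_oracle_three_taxa(self):
        m = DistanceMatrix(("A", "B", "C"),
                           np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], float))
        t = upgma(m)
        depths = t.tip_depths()
        assert np.allclose(depths.to_numpy(), 3.0)
        # A and B join at height 1 (branch 1 each), C at 3
        P = t.patristic_matrix(["A", "B", "C"])
        assert P[0, 1] == pytest.approx(2.0)
        assert P[0, 2] == pytest.approx(6.0)

    def test_two_taxa(self):
        m = DistanceMatrix(("A", "B"), np.array([[0, 1], [1, 0]], float))
        t = upgma(m)
        assert np.allclose(t.tip_depths().to_numpy(), 0.5)

    def test_output_is_ultrametric_for_random_input(self):
        rng = np.random.default_rng(4)
        n = 12
        v = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        v[iu] = rng.random(len(iu[0])) + 0.1
        v = v + v.T
        t = upgma(DistanceMatrix(tuple(f"t{i}" for i in range(n)), v))
        assert t.is_ultrametric(rel_tol=1e-9)

    def test_agrees_with_scipy_average_linkage_heights(self):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(6)
        n = 10
        v = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        v[iu] = rng.random(len(iu[0])) + 0.1
        v = v + v.T
        t = upgma(DistanceMatrix(tuple(f"t{i}" for i in range(n)), v))
        Z = average(squareform(v))
        # cophenetic heights of the deepest merge agree (root depth = max/2)
        assert max(t.tip_depths()) == pytest.approx(Z[-1, 2] / 2)


class TestNeighborJoining:
    def test_recovers_additive_four_taxon_tree(self):
        # tree ((A:2,B:3):1,(C:4,D:5):1) -> additive distances
        src = PhyloTree.from_newick("((A:2,B:3):1,(C:4,D:5):1);")
        labs = ["A", "B", "C", "D"]
        v = src.patristic_matrix(labs)
        t = neighbor_joining(DistanceMatrix(tuple(labs), v))
        rec = t.patristic_matrix(labs)
        assert np.allclose(rec, v, atol=1e-6)

    def test_three_taxon_closed_form(self):
        v = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        t = neighbor_joining(DistanceMatrix(("A", "B", "C"), v))
        rec = t.patristic_matrix(["A", "B", "C"])
        assert np.allclose(rec, v, atol=1e-6)

    def test_ultrametric_input_matches_upgma_topology(self):
        src = PhyloTree.from_newick("((A:1,B:1):3,(C:2,D:2):2);")
        labs = ["A", "B", "C", "D"]
        m = DistanceMatrix(tuple(labs), src.patristic_matrix(labs))
        nj_pat = neighbor_joining(m).patristic_matrix(labs)
        up_pat = upgma(m).patristic_matrix(labs)
        # same sister pairs: A-B and C-D closest in both
        assert nj_pat[0, 1] == min(nj_pat[0, 1:])
        assert up_pat[0, 1] == min(up_pat[0, 1:])
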