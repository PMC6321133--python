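"""Microbiome stage: rarefaction, diversity, UniFrac, ordination, ANOSIM,
LDA effect size and metagenome prediction."""

import io
import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode

import _oracles as orc
from metabologenomics import (FeatureTable, PhyloTree, alpha_diversity, anosim,
                              lda_effect_size, pcoa, predict_metagenome,
                              rarefy, relative_abundance, top_taxa, unifrac)
from metabologenomics.tables_io import GeneContentReference


def _counts(values, prefix="g"):
    arr = np.asarray(values)
    return FeatureTable(
        pd.DataFrame(arr, index=[f"s{i}" for i in range(arr.shape[0])],
                     columns=[f"{prefix}{j}" for j in range(arr.shape[1])]),
        block="taxon", unit="count")


def _tree(newick):
    return PhyloTree(TreeNode.read(io.StringIO(newick)))


class TestRarefy:
    def test_output_rows_sum_to_depth(self):
        rng = np.random.default_rng(0)
        tbl = _counts(rng.integers(0, 2000, size=(4, 30)) + 500)
        out = rarefy(tbl, depth=10_000, seed=1)
        assert (out.data.sum(axis=1) == 10_000).all()

    def test_depth_equal_to_total_is_identity(self):
        tbl = _counts([[5, 3, 2]])
        out = rarefy(tbl, depth=10, seed=0)
        assert (out.data.to_numpy() == tbl.data.to_numpy()).all()

    def test_shallow_samples_dropped(self):
        tbl = _counts([[10, 10], [2, 2]])
        out = rarefy(tbl, depth=15, seed=0)
        assert out.sample_ids == ["s0"]

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError):
            rarefy(_counts([[5, 5]]), depth=0)

    def test_sampling_distribution_preserves_proportions(self):
        """Expected rarefied count of a taxon tracks its original proportion
        (hypergeometric mean), averaged over many seeds."""
        tbl = _counts([[600, 300, 100]])
        depth = 500
        draws = np.array([
            rarefy(tbl, depth=depth, seed=s).data.to_numpy()[0]
            for s in range(1000)])
        expected = depth * np.array([600, 300, 100]) / 1000
        assert np.allclose(draws.mean(axis=0), expected, rtol=0.02)


class TestRelativeAbundance:
    def test_simple_fractions(self):
        out = relative_abundance(_counts([[2, 2]]))
        assert np.allclose(out.data.to_numpy(), [[0.5, 0.5]])

    def test_scale_invariance(self):
        a = relative_abundance(_counts([[3, 7, 10]]))
        b = relative_abundance(_counts([[30, 70, 100]]))
        assert np.allclose(a.data.to_numpy(), b.data.to_numpy())

    def test_rows_sum_to_one(self, dataset):
        out = relative_abundance(dataset.counts)
        assert np.allclose(out.data.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_sum_row_rejected(self):
        with pytest.raises(ValueError):
            relative_abundance(_counts([[0, 0]]))

    def test_top_taxa_at_one_percent(self):
        # constructed so g0 (50%), g1 (30%) pass and g2 (0.5%) fails
        tbl = _counts([[500, 300, 5, 195]])
        rel = relative_abundance(tbl)
        assert top_taxa(rel, min_mean=0.01) == ["g0", "g1", "g3"]


class TestAlphaDiversity:
    def test_uniform_sample_shannon(self):
        out = alpha_diversity(_counts([[5, 5, 5, 5]]))
        assert out.loc["s0", "shannon"] == pytest.approx(np.log(4))
        assert out.loc["s0", "observed"] == 4

    def test_chao1_equals_observed_without_rare_taxa(self):
        out = alpha_diversity(_counts([[10, 10, 10]]))
        assert out.loc["s0", "chao1"] == pytest.approx(3.0)

    def test_chao1_formula_arithmetic(self):
        # S=5, F1=2 (two singletons), F2=1 -> chao1 = 5 + 2*1/(2*2) = 5.5
        out = alpha_diversity(_counts([[1, 1, 2, 5, 9]]))
        assert out.loc["s0", "chao1"] == pytest.approx(5.5)

    def test_non_integer_counts_rejected(self):
        tbl = FeatureTable(pd.DataFrame([[1.5, 2.0]], index=["s0"],
                                        columns=["g0", "g1"]), "taxon", "count")
        with pytest.raises(ValueError):
            alpha_diversity(tbl)


class TestUnifrac:
    def test_identical_communities_distance_zero(self):
        tree = _tree("((g0:1,g1:2):1,g2:1);")
        tbl = _counts([[3, 1, 2], [3, 1, 2]])
        assert unifrac(tbl, tree)[0, 1] == pytest.approx(0.0)
        assert unifrac(tbl, tree, weighted=True)[0, 1] == pytest.approx(0.0)

    def test_disjoint_singletons_on_star_tree(self):
        # star topology (zero-length internal branch), unit tip branches
        tree = _tree("((g0:1,g1:1):0,g2:1);")
        tbl = _counts([[1, 0, 0], [0, 1, 0]])
        assert unifrac(tbl, tree)[0, 1] == pytest.approx(1.0)

    def test_hand_enumerated_three_leaf_tree(self):
        # branches: A:1, B:1, internal:1, C:2; samples {A} vs {C}
        tree = _tree("((g0:1,g1:1):1,g2:2);")
        tbl = _counts([[1, 0, 0], [0, 0, 1]])
        assert unifrac(tbl, tree)[0, 1] == pytest.approx((1 + 1 + 2) / (1 + 1 + 2))
        assert unifrac(tbl, tree, weighted=True)[0, 1] == pytest.approx(4.0)
        assert unifrac(tbl, tree, weighted=True, normalized=True)[0, 1] == \
            pytest.approx(1.0)

    def test_missing_taxon_reported(self):
        tree = _tree("(g0:1,g1:1);")
        tbl = _counts([[1, 0, 2], [0, 1, 1]])
        with pytest.raises(ValueError, match="g2"):
            unifrac(tbl, tree)

    def test_matches_branch_walk_oracle_on_random_trees(self):
        """Implementation equals the exhaustive branch-walk oracle for random
        4-leaf topologies and random abundance vectors, all variants."""
        rng = np.random.default_rng(42)
        leaves = ("g0", "g1", "g2", "g3")
        topos = list(orc.enumerate_rooted_binary_trees(leaves))
        for topo in topos[::3]:
            tree_t = orc.assign_lengths(topo, rng)
            nwk = orc.to_newick(tree_t)
            tree = _tree(nwk)
            ab = rng.integers(0, 5, size=(2, 4))
            if (ab.sum(axis=1) == 0).any():
                continue
            tbl = _counts(ab)
            a = dict(zip(leaves, ab[0]))
            b = dict(zip(leaves, ab[1]))
            if (ab[0] > 0).any() and (ab[1] > 0).any():
                assert unifrac(tbl, tree)[0, 1] == pytest.approx(
                    orc.branch_walk_unifrac(tree_t, a, b), abs=1e-10)
                assert unifrac(tbl, tree, weighted=True)[0, 1] == pytest.approx(
                    orc.branch_walk_unifrac(tree_t, a, b, weighted=True),
                    abs=1e-10)

    def test_unweighted_triangle_inequality_on_binary_profiles(self):
        rng = np.random.default_rng(5)
        leaves = ("g0", "g1", "g2", "g3", "g4")
        topo = next(orc.enumerate_rooted_binary_trees(leaves))
        tree = _tree(orc.to_newick(orc.assign_lengths(topo, rng)))
        profiles = [p for p in itertools.product([0, 1], repeat=5) if any(p)]
        idx = rng.choice(len(profiles), size=8, replace=False)
        tbl = _counts([profiles[i] for i in idx])
        d = unifrac(tbl, tree)
        arr = np.asarray(d.data)
        n = arr.shape[0]
        for i, j, k in itertools.permutations(range(n), 3):
            assert arr[i, j] <= arr[i, k] + arr[k, j] + 1e-12


class TestPcoa:
    def test_recovers_planar_configuration(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(12, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(d, [f"s{i}" for i in range(12)])
        res = pcoa(dm, k=2)
        from metabologenomics import procrustes
        m2 = procrustes(pd.DataFrame(pts, index=res.scores.index),
                        res.scores, k=2).m2
        assert m2 < 1e-10

    def test_duplicate_samples_coincide(self):
        d = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]])
        dm = DistanceMatrix(d, ["a", "b", "c"])
        res = pcoa(dm)
        assert np.allclose(res.scores.loc["a"], res.scores.loc["b"], atol=1e-9)

    def test_eigenvalues_sorted_and_negatives_reported(self):
        # triangle-violating distances guarantee a negative eigenvalue
        d = np.array([[0.0, 3.0, 1.0, 1.0], [3.0, 0.0, 1.0, 1.0],
                      [1.0, 1.0, 0.0, 1.0], [1.0, 1.0, 1.0, 0.0]])
        dm = DistanceMatrix(d, list("abcd"))
        res = pcoa(dm)
        ev = res.eigvals.to_numpy()
        assert (np.diff(ev) <= 1e-12).all()
        assert ev.min() < 0  # reported, not dropped


class TestAnosim:
    def _dm(self, d, ids):
        return DistanceMatrix(d, ids)

    def test_perfect_separation_gives_r_one(self):
        d = np.zeros((4, 4))
        within, between = 0.1, 5.0
        for i, j in itertools.combinations(range(4), 2):
            same = (i < 2) == (j < 2)
            d[i, j] = d[j, i] = within if same else between
        g = pd.Series(["a", "a", "b", "b"], index=list("wxyz"))
        res = anosim(self._dm(d, list("wxyz")), g, n_perm=99, seed=0)
        assert res.R == pytest.approx(1.0)

    def test_two_per_group_hand_ranks(self):
        # distances chosen with distinct values; ranks computed by hand:
        # within pairs {1.0, 2.0} -> ranks {1, 2}; between {3,4,5,6} -> 3..6
        d = np.zeros((4, 4))
        d[0, 1] = d[1, 0] = 1.0
        d[2, 3] = d[3, 2] = 2.0
        vals = iter([3.0, 4.0, 5.0, 6.0])
        for i, j in [(0, 2), (0, 3), (1, 2), (1, 3)]:
            v = next(vals)
            d[i, j] = d[j, i] = v
        g = pd.Series(["a", "a", "b", "b"], index=list("wxyz"))
        res = anosim(self._dm(d, list("wxyz")), g, n_perm=99, seed=0)
        # mean between rank 4.5, mean within rank 1.5, M/2 = 3
        assert res.R == pytest.approx((4.5 - 1.5) / 3.0)

    def test_matches_skbio_statistic(self):
        from skbio.stats.distance import anosim as sk_anosim
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        pts[5:] += 1.0
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(10)]
        g = pd.Series(["a"] * 5 + ["b"] * 5, index=ids)
        ours = anosim(self._dm(d, ids), g, n_perm=99, seed=1)
        ref = sk_anosim(self._dm(d, ids), g.to_frame("g"), column="g",
                        permutations=0)
        assert ours.R == pytest.approx(float(ref["test statistic"]))

    def test_no_structure_r_near_zero(self):
        rng = np.random.default_rng(3)
        rs, ps = [], []
        ids = [f"s{i}" for i in range(12)]
        for rep in range(20):
            pts = rng.normal(size=(12, 3))
            d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
            g = pd.Series(["a"] * 6 + ["b"] * 6, index=ids)
            res = anosim(DistanceMatrix(d, ids), g, n_perm=99, seed=rep)
            rs.append(res.R)
            ps.append(res.p)
        assert abs(np.mean(rs)) < 0.1
        assert 0.2 < np.mean(ps)  # p roughly uniform under the null

    def test_single_group_rejected(self):
        d = np.array([[0, 1.0], [1.0, 0]])
        g = pd.Series(["a", "a"], index=["x", "y"])
        with pytest.raises(ValueError):
            anosim(DistanceMatrix(d, ["x", "y"]), g)


class TestLdaEffectSize:
    def test_separated_feature_reported_with_direction(self):
        rng = np.random.default_rng(0)
        n = 20
        rel = np.full((n, 3), 0.2)
        rel[:10, 0] = 0.002   # 100-fold lower in group "a"
        rel[10:, 0] = 0.2
        rel += rng.uniform(0, 0.01, size=rel.shape)
        rel /= rel.sum(axis=1, keepdims=True)
        tbl = FeatureTable(pd.DataFrame(
            rel, index=[f"s{i}" for i in range(n)],
            columns=["marker", "g1", "g2"]), "taxon", "fraction")
        g = pd.Series(["a"] * 10 + ["b"] * 10, index=tbl.sample_ids)
        hits = lda_effect_size(tbl, g, seed=0)
        names = {h.feature: h for h in hits}
        assert "marker" in names
        assert names["marker"].direction == "b"
        assert names["marker"].lda_score > 2.0

    def test_identical_distributions_not_reported(self):
        rng = np.random.default_rng(1)
        rel = rng.dirichlet(np.ones(4), size=16)
        tbl = FeatureTable(pd.DataFrame(
            rel, index=[f"s{i}" for i in range(16)],
            columns=[f"g{j}" for j in range(4)]), "taxon", "fraction")
        g = pd.Series(["a"] * 8 + ["b"] * 8, index=tbl.sample_ids)
        assert lda_effect_size(tbl, g, seed=0) == []

    def test_infinite_threshold_empty(self, dataset):
        relab = relative_abundance(dataset.counts)
        out = lda_effect_size(relab, dataset.meta.groups,
                              threshold=np.inf, seed=0)
        assert out == []


class TestPredictMetagenome:
    def _ref(self):
        cn = pd.Series([2, 1], index=["g0", "g1"])
        ko = pd.DataFrame([[3.0, 0.0], [1.0, 1.0]], index=["g0", "g1"],
                          columns=["K1", "K2"])
        return GeneContentReference(cn, ko, {"K1": {"p1"}, "K2": {"p1", "p2"}})

    def test_copy_number_normalised_arithmetic(self):
        out = predict_metagenome(_counts([[10, 0]]), self._ref())
        # 10 reads / copy number 2 = 5 organisms x 3 copies of K1 = 15
        assert out.ko_table.data.loc["s0", "K1"] == pytest.approx(15.0)

    def test_unit_copy_numbers_give_plain_product(self):
        ref = self._ref()
        ref.copy_number[:] = 1
        tbl = _counts([[4, 6]])
        out = predict_metagenome(tbl, ref)
        expected = tbl.data.to_numpy() @ ref.ko_content.to_numpy()
        assert np.allclose(out.ko_table.data.to_numpy(), expected)

    def test_linearity_in_counts(self):
        ref = self._ref()
        a = predict_metagenome(_counts([[4, 6]]), ref).ko_table.data
        b = predict_metagenome(_counts([[8, 12]]), ref).ko_table.data
        assert np.allclose(2 * a.to_numpy(), b.to_numpy())

    def test_pathway_sums_respect_multiplicity(self):
        out = predict_metagenome(_counts([[10, 10]]), self._ref())
        ko = out.ko_table.data
        pw = out.pathway_table.data
        assert pw.loc["s0", "p1"] == pytest.approx(ko.loc["s0", "K1"] +
                                                   ko.loc["s0", "K2"])
        assert pw.loc["s0", "p2"] == pytest.approx(ko.loc["s0", "K2"])

    def test_missing_taxon_strict_vs_lenient(self):
        tbl = _counts([[1, 1, 1]])
        with pytest.raises(ValueError):
            predict_metagenome(tbl, self._ref(), strict=True)
        out = predict_metagenome(tbl, self._ref(), strict=False)
        assert out.ko_table.shape == (1, 2)
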