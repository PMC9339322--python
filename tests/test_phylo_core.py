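"""Tree I/O, de-replication, depths, contrasts, and the fat-tail
diagnostic."""

import dendropy
import numpy as np
import pytest

from gcjump.errors import GCJumpError, NewickFormatError, PolytomyError
from gcjump.phylo_core import (
    excess_kurtosis,
    newick_from_string,
    node_depths,
    pic_contrasts,
    read_trait_table,
    resolve_polytomies,
    shared_path_matrix,
    subsample_tree,
    validate_traits,
    write_newick,
    write_trait_table,
)
from gcjump.synthetic_data import simulate_yule_tree

from conftest import star_tree, tip_path_lengths


class TestNewickIO:
    def test_minimal_tree_structure(self, three_tip_tree):
        t = three_tip_tree
        assert t.n_tips == 3
        assert sorted(t.tip_labels()) == ["A", "B", "C"]
        assert len(t.children[t.root]) == 2

    @pytest.mark.parametrize(
        "newick",
        [
            "((A:1,B:1):1,C:2);",
            "(A:1,B:1);",
            "((A:0.5,B:0.25):0.1,(C:2,D:0.3):0.7);",
            "((A:1,B:2,C:3):1,D:4);",  # polytomy preserved
        ],
    )
    def test_round_trip_identity(self, newick):
        t1 = newick_from_string(newick)
        t2 = newick_from_string(write_newick(t1))
        assert t1.labels == t2.labels
        assert np.array_equal(t1.parent, t2.parent)
        np.testing.assert_allclose(t1.blen, t2.blen, rtol=1e-12)

    def test_malformed_input_names_offset(self):
        with pytest.raises(NewickFormatError):
            newick_from_string("((A:1,B:1)")

    def test_missing_branch_length_is_an_error(self):
        with pytest.raises(NewickFormatError, match="branch length"):
            newick_from_string("((A:1,B):1,C:2);")

    def test_annotation_comment_dialect(self, three_tip_tree):
        out = write_newick(three_tip_tree, branch_annotations={1: 0.97})
        assert "[&pp=0.97]" in out
        # a reader that ignores comments recovers the same topology
        t2 = newick_from_string(out)
        assert t2.labels == three_tip_tree.labels

    def test_annotation_on_non_branch_rejected(self, three_tip_tree):
        with pytest.raises(GCJumpError):
            write_newick(three_tip_tree, branch_annotations={0: 0.5})

    def test_trait_table_round_trip(self, tmp_path):
        traits = {"A": 41.5, "B": 63.25}
        write_trait_table(traits, tmp_path / "gc.tsv")
        assert read_trait_table(tmp_path / "gc.tsv") == traits

    def test_trait_table_rejects_out_of_range(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("tip_label\tgc_percent\nA\t140\n")
        with pytest.raises(GCJumpError):
            read_trait_table(tmp_path / "bad.tsv")


class TestSubsample:
    def test_collapses_young_cherry(self):
        t = newick_from_string("((A:0.001,B:0.002):0.5,C:0.6);")
        out = subsample_tree(t, 0.01)
        assert sorted(out.tip_labels()) == ["A", "C"]  # lexicographic rep

    def test_no_op_when_all_clades_old(self, three_tip_tree):
        out = subsample_tree(three_tip_tree, 1e-6)
        assert sorted(out.tip_labels()) == ["A", "B", "C"]

    def test_branch_lengths_summed_through_removed_nodes(self):
        t = newick_from_string("((A:0.001,B:0.002):0.5,C:0.6);")
        out = subsample_tree(t, 0.01)
        depths = dict(zip(out.labels, node_depths(out)))
        assert depths["A"] == pytest.approx(0.501)
        assert depths["C"] == pytest.approx(0.6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_postcondition_and_idempotency_on_random_trees(self, seed):
        tree = simulate_yule_tree(100, seed=seed, mean_tip_depth=0.2)
        thr = 0.05
        out = subsample_tree(tree, thr)
        # exhaustive post-check: no surviving internal node is younger than
        # the threshold while retaining >1 tip
        heights = out.clade_heights()
        for v in range(out.n_nodes):
            if not out.is_tip[v] and heights[v] < thr:
                assert out.subtree_tips(v).size == 1
        again = subsample_tree(out, thr)
        assert again.labels == out.labels
        np.testing.assert_allclose(again.blen, out.blen)


class TestDepthsAndPaths:
    def test_depth_additivity(self, three_tip_tree):
        d = dict(zip(three_tip_tree.labels, node_depths(three_tip_tree)))
        assert d["A"] == 2 and d["B"] == 2 and d["C"] == 2
        internal = node_depths(three_tip_tree)[1]
        assert internal == 1.0

    def test_star_tree_uniform_depths(self):
        t = star_tree(7, depth=0.3)
        np.testing.assert_allclose(node_depths(t)[t.tip_indices()], 0.3)

    def test_depths_match_dendropy_oracle(self):
        tree = simulate_yule_tree(40, seed=5, jitter_sd=0.4, mean_tip_depth=0.7)
        nwk = write_newick(tree)
        dt = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
        oracle = {
            leaf.taxon.label: leaf.distance_from_root()
            for leaf in dt.leaf_node_iter()
        }
        depths = node_depths(tree)
        for t_idx in tree.tip_indices():
            assert depths[t_idx] == pytest.approx(oracle[tree.labels[t_idx]])

    def test_parent_child_depth_differences_are_branch_lengths(self):
        tree = simulate_yule_tree(60, seed=9, jitter_sd=0.2)
        d = node_depths(tree)
        for v in range(1, tree.n_nodes):
            assert abs(d[v] - d[tree.parent[v]] - tree.blen[v]) < 1e-12

    def test_shared_path_matrix_against_parent_walk(self):
        tree = simulate_yule_tree(25, seed=2, jitter_sd=0.5)
        np.testing.assert_allclose(
            shared_path_matrix(tree), tip_path_lengths(tree), rtol=1e-12
        )


class TestContrasts:
    def test_two_tip_closed_form(self, cherry):
        cs = pic_contrasts(cherry, {"A": 0.0, "B": 2.0})
        assert len(cs) == 1
        assert abs(cs.contrasts[0]) == pytest.approx(np.sqrt(2.0))

    def test_constant_traits_give_zero_contrasts(self, three_tip_tree):
        cs = pic_contrasts(three_tip_tree, {"A": 5.0, "B": 5.0, "C": 5.0})
        np.testing.assert_allclose(cs.contrasts, 0.0)
        assert len(cs) == three_tip_tree.n_tips - 1

    def test_polytomy_rejected_with_guidance(self):
        t = newick_from_string("((A:1,B:2,C:3):1,D:4);")
        with pytest.raises(PolytomyError, match="resolve_polytomies"):
            pic_contrasts(t, {"A": 1, "B": 2, "C": 3, "D": 4})

    def test_missing_trait_rejected(self, three_tip_tree):
        with pytest.raises(GCJumpError):
            pic_contrasts(three_tip_tree, {"A": 1.0, "B": 2.0})

    def test_bm_simulation_contrast_variance_near_rate(self):
        # under Brownian motion with unit rate, scaled contrasts are iid
        # N(0, 1); pool across replicates and check the sample variance
        from gcjump.levy_model import LevyParams, simulate_levy

        rng_seeds = range(20)
        pooled = []
        for s in rng_seeds:
            tree = simulate_yule_tree(100, seed=300 + s, jitter_sd=0.2)
            traits, _ = simulate_levy(tree, LevyParams(1.0, 0.0, 1.0, 0.0), seed=s)
            pooled.extend(pic_contrasts(tree, traits).contrasts.tolist())
        v = np.var(pooled)
        assert abs(v - 1.0) < 0.1

    def test_levy_contrasts_are_fat_tailed(self):
        # jump-contaminated evolution should push contrast kurtosis above 0
        from gcjump.levy_model import LevyParams, simulate_levy

        kurts = []
        for s in range(8):
            tree = simulate_yule_tree(150, seed=800 + s, jitter_sd=0.2)
            traits, _ = simulate_levy(
                tree, LevyParams(1.0, 0.3, 8.0, 0.0), seed=s
            )
            kurts.append(excess_kurtosis(pic_contrasts(tree, traits).contrasts))
        assert np.median(kurts) > 0.5


class TestExcessKurtosis:
    def test_two_point_symmetric_value(self):
        assert excess_kurtosis([-1, 1, -1, 1]) == pytest.approx(-2.0)

    def test_gaussian_and_laplace_large_sample(self):
        rng = np.random.default_rng(12)
        assert abs(excess_kurtosis(rng.standard_normal(100_000))) < 0.1
        assert excess_kurtosis(rng.laplace(size=100_000)) == pytest.approx(3.0, abs=0.2)

    @pytest.mark.parametrize("bad", [[1.0, 2.0, 3.0], [4.0] * 10])
    def test_degenerate_inputs_rejected(self, bad):
        with pytest.raises(GCJumpError):
            excess_kurtosis(bad)


def test_resolve_polytomies_preserves_tip_covariance():
    t = newick_from_string("((A:1,B:2,C:3):1,D:4,E:1);")
    r = resolve_polytomies(t)
    assert r.is_binary()
    orig = shared_path_matrix(t)
    # tip order may change; compare via label-indexed lookup
    lab_o = [t.labels[i] for i in t.tip_indices()]
    lab_r = [r.labels[i] for i in r.tip_indices()]
    res = shared_path_matrix(r)
    idx = [lab_r.index(l) for l in lab_o]
    np.testing.assert_allclose(orig, res[np.ix_(idx, idx)], atol=1e-12)


def test_validate_traits_orders_by_tip_index(three_tip_tree):
    x = validate_traits(three_tip_tree, {"A": 1.0, "B": 2.0, "C": 3.0})
    labels = three_tip_tree.tip_labels()
    assert list(x) == [{"A": 1.0, "B": 2.0, "C": 3.0}[l] for l in labels]


class TestKurtosisProperties:
    from hypothesis import given, settings, strategies as st

    @given(
        seed=st.integers(min_value=0, max_value=10_000),
        shift=st.floats(-50, 50, allow_nan=False),
        scale=st.floats(0.1, 10, allow_nan=False),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_affine_invariance(self, seed, shift, scale):
        # excess kurtosis is location/scale free
        v = np.random.default_rng(seed).standard_normal(50)
        k1 = excess_kurtosis(v)
        k2 = excess_kurtosis(scale * v + shift)
        assert k2 == pytest.approx(k1, rel=1e-6, abs=1e-8)
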