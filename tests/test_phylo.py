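"""NJ trees, bootstrap, concatenation and PD reduction."""

import itertools
import random

import numpy as np
import pytest
from skbio import DistanceMatrix

from gablocks.phylo import (
    CONCAT_ORDER,
    UndefinedDistanceError,
    bootstrap_support,
    concat_operon,
    nj_tree,
    p_distance,
    pd_reduce,
    root_with_outgroup,
    split_fusion_slots,
    subset_pd,
    _bipartitions,
)
from gablocks.simulate import sample_tree


def _splits(tree):
    taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    return _bipartitions(tree, taxa)


class TestPDistance:
    def test_identical_rows_are_zero(self):
        dm = p_distance({"x": "MKLV", "y": "MKLV"})
        assert dm["x", "y"] == 0.0

    def test_single_mismatch(self):
        assert p_distance({"x": "MKL", "y": "MTL"})["x", "y"] == pytest.approx(1 / 3)

    def test_gap_columns_are_skipped_pairwise(self):
        dm = p_distance({"x": "M-LV", "y": "MKLA"})
        assert dm["x", "y"] == pytest.approx(1 / 3)

    def test_matches_column_loop_oracle_on_random_alignment(self):
        rng = random.Random(11)
        ids = [f"s{i}" for i in range(10)]
        aln = {
            i: "".join(rng.choice("ACDEFGH-") for _ in range(50)) for i in ids
        }
        try:
            dm = p_distance(aln)
        except UndefinedDistanceError:
            pytest.skip("degenerate random alignment")
        for a, b in itertools.combinations(ids, 2):
            mism = comp = 0
            for x, y in zip(aln[a], aln[b]):
                if x == "-" or y == "-":
                    continue
                comp += 1
                mism += x != y
            assert dm[a, b] == pytest.approx(mism / comp)

    def test_no_comparable_columns_is_an_error(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance({"x": "M-", "y": "-K"})


class TestNJ:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix([[0, 0.3, 0.5], [0.3, 0, 0.4], [0.5, 0.4, 0]], ["A", "B", "C"])
        tree = nj_tree(dm)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.4) / 2)
        assert lengths["B"] == pytest.approx((0.3 + 0.4 - 0.5) / 2)
        assert lengths["C"] == pytest.approx((0.5 + 0.4 - 0.3) / 2)

    def test_additive_four_taxon_topology_and_internal_edge(self):
        dm = DistanceMatrix(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]],
            ["A", "B", "C", "D"],
        )
        tree = nj_tree(dm)
        assert frozenset(["A", "B"]) in _splits(tree) or frozenset(["C", "D"]) in _splits(tree)
        internal = [
            e.length
            for e in tree.preorder_edge_iter()
            if e.head_node is not None
            and not e.head_node.is_leaf()
            and e.length
        ]
        assert pytest.approx(max(internal)) == 2.0

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix([[0, 1], [1, 0]], ["A", "B"]))

    def test_taxon_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(0)
        tree = sample_tree(7, 1.0, 42)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
        ids = [t.label for t in taxa]
        mat = np.array([[pdm.patristic_distance(a, b) for b in taxa] for a in taxa])
        t1 = nj_tree(DistanceMatrix(mat, ids))
        perm = list(rng.permutation(len(ids)))
        t2 = nj_tree(DistanceMatrix(mat[np.ix_(perm, perm)], [ids[i] for i in perm]))
        assert _splits(t1) == _splits(t2)

    def test_additive_matrices_recover_generating_topology(self):
        for seed in range(30):
            true_tree = sample_tree(8, 1.0, seed)
            pdm = true_tree.phylogenetic_distance_matrix()
            taxa = sorted(true_tree.taxon_namespace, key=lambda t: t.label)
            ids = [t.label for t in taxa]
            mat = [[pdm.patristic_distance(a, b) for b in taxa] for a in taxa]
            est = nj_tree(DistanceMatrix(mat, ids))
            assert _splits(est) == _splits(true_tree), f"seed {seed}"


class TestRooting:
    def test_root_on_outgroup_edge(self):
        dm = DistanceMatrix(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]],
            ["A", "B", "C", "OUT"],
        )
        rooted = root_with_outgroup(nj_tree(dm), "OUT")
        root_children = rooted.seed_node.child_nodes()
        assert len(root_children) == 2
        sides = [
            {l.taxon.label for l in c.leaf_iter()} for c in root_children
        ]
        assert {"OUT"} in sides

    def test_missing_outgroup_raises(self):
        dm = DistanceMatrix([[0, 1, 2], [1, 0, 2], [2, 2, 0]], ["A", "B", "C"])
        with pytest.raises(LookupError):
            root_with_outgroup(nj_tree(dm), "Z")

    def test_rooting_preserves_unrooted_topology(self):
        tree = sample_tree(7, 1.0, 3)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
        ids = [t.label for t in taxa]
        mat = [[pdm.patristic_distance(a, b) for b in taxa] for a in taxa]
        unrooted = nj_tree(DistanceMatrix(mat, ids))
        rooted = root_with_outgroup(unrooted, ids[0])
        assert _splits(rooted) == _splits(unrooted)


class TestBootstrap:
    aln = {
        "A": "AAAAAAAAAAGGGGGGGGGG",
        "B": "AAAAAAAAAAGGGGGGGGGC",
        "C": "TTTTTTTTTTGGGGGGGGGG",
        "D": "TTTTTTTTTTGGGGGGGGCC",
    }

    def test_clear_signal_gets_full_support(self):
        tree = bootstrap_support(self.aln, 50, seed=1)
        labels = [
            n.label
            for n in tree.preorder_internal_node_iter()
            if n.label is not None
        ]
        assert "100.0" in labels

    def test_seed_determinism(self):
        t1 = bootstrap_support(self.aln, 30, seed=5).as_string(schema="newick")
        t2 = bootstrap_support(self.aln, 30, seed=5).as_string(schema="newick")
        assert t1 == t2

    def test_supports_match_recount_from_replicates(self):
        tree, reps = bootstrap_support(
            self.aln, 40, seed=2, return_replicates=True
        )
        taxa = frozenset(self.aln)
        for node in tree.preorder_internal_node_iter():
            if node.label is None:
                continue
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            if min(taxa) in below:
                below = taxa - below
            count = sum(1 for rep in reps if below in _bipartitions(rep, taxa))
            assert float(node.label) == pytest.approx(100.0 * count / 40)


class TestConcat:
    def test_concatenation_in_fixed_order(self):
        seqs = {lbl: lbl.upper() * 3 for lbl in CONCAT_ORDER}
        concat, excluded = concat_operon({"G1": seqs})
        assert concat["G1"] == "".join(l.upper() * 3 for l in CONCAT_ORDER)
        assert excluded == {}

    def test_missing_family_excludes_genome_with_reason(self):
        seqs = {lbl: "AAA" for lbl in CONCAT_ORDER if lbl != "h"}
        concat, excluded = concat_operon({"G1": seqs})
        assert concat == {} and excluded == {"G1": ["h"]}

    def test_fusion_sequence_splits_into_slots(self):
        c_part, d_part = "C" * 90, "D" * 30
        fused = c_part + d_part
        slots = split_fusion_slots(fused, ("c", "d"), (91, 120))
        assert slots == {"c": c_part, "d": d_part}
        d_part2, e_part = "D" * 30, "E" * 60
        slots = split_fusion_slots(d_part2 + e_part, ("d", "e"), (1, 30))
        assert slots == {"d": d_part2, "e": e_part}


class TestPDReduce:
    def test_k_equals_n_selects_everything(self):
        tree = sample_tree(8, 1.0, 1)
        labels = {l.taxon.label for l in tree.leaf_node_iter()}
        subset = pd_reduce(tree, 8)
        assert subset == labels
        assert subset_pd(tree, subset) == pytest.approx(
            sum(e.length or 0 for e in tree.preorder_edge_iter() if e.head_node.parent_node is not None)
        )

    def test_k2_picks_the_most_distant_pair(self):
        for seed in range(10):
            tree = sample_tree(7, 1.0, seed)
            pdm = tree.phylogenetic_distance_matrix()
            taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
            best = max(
                itertools.combinations(taxa, 2),
                key=lambda p: pdm.patristic_distance(*p),
            )
            assert pd_reduce(tree, 2) == {t.label for t in best}

    @pytest.mark.parametrize("seed", range(10))
    def test_greedy_equals_exhaustive_optimum(self, seed):
        tree = sample_tree(9, 1.0, seed)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        for k in (3, 5, 7):
            greedy = subset_pd(tree, pd_reduce(tree, k))
            best = max(
                subset_pd(tree, set(combo))
                for combo in itertools.combinations(labels, k)
            )
            assert greedy == pytest.approx(best)

    def test_mandatory_keep_labels_are_retained(self):
        tree = sample_tree(8, 1.0, 4)
        labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
        subset = pd_reduce(tree, 4, keep=(labels[0], labels[1]))
        assert {labels[0], labels[1]} <= subset

    def test_k_out_of_range(self):
        tree = sample_tree(5, 1.0, 0)
        with pytest.raises(ValueError):
            pd_reduce(tree, 1)
        with pytest.raises(ValueError):
            pd_reduce(tree, 6)
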