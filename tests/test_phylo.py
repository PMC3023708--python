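import numpy as np
import pytest

from bcescan.errors import InputError
from bcescan.clustering import ModuleCluster
from bcescan.io import GeneFeature, parse_newick
from bcescan.phylo import (
    Tree,
    assign_subfamily,
    concordance,
    is_monophyletic,
    nj_tree,
    rf_distance,
)
from bcescan.simulate import (
    SimConfig,
    patristic_matrix,
    plant_reference_trees,
    random_tree,
    reference_map_for,
)


class TestMonophyly:
    def test_true_clade(self):
        tree = parse_newick("((A,B),(C,D));")
        ok, support = is_monophyletic(tree, {"A", "B"})
        assert ok and support == 1.0

    def test_non_clade(self):
        tree = parse_newick("((A,B),(C,D));")
        ok, _ = is_monophyletic(tree, {"A", "C"})
        assert not ok

    def test_support_reported(self):
        tree = parse_newick("((A,B)0.97,(C,D));")
        ok, support = is_monophyletic(tree, {"A", "B"})
        assert ok and support == pytest.approx(0.97)

    def test_unknown_label_is_error(self):
        tree = parse_newick("((A,B),(C,D));")
        with pytest.raises(InputError, match="Z"):
            is_monophyletic(tree, {"A", "Z"})

    def test_unrooted_semantics_sees_complement(self):
        # {C,D,E} is the complement of {A,B} across one edge
        tree = parse_newick("((A,B)0.9,(C,(D,E)));")
        ok, support = is_monophyletic(tree, {"C", "D", "E"})
        assert ok and support == pytest.approx(0.9)


class TestAssignSubfamily:
    REFS = {"R4a": "IV", "R4b": "IV", "R2": "II", "R5": "V"}

    def test_query_sister_to_reference(self):
        tree = parse_newick("(((Q,R4a)1.0,R4b)1.0,(R2,R5)1.0);")
        call = assign_subfamily(tree, "Q", self.REFS)
        assert call.subfamily == "IV"
        assert call.support == pytest.approx(1.0)

    def test_mixed_clade_is_unclassified(self):
        tree = parse_newick("(((Q,R2,R5)1.0,X)1.0,(R4a,R4b)1.0);")
        call = assign_subfamily(tree, "Q", self.REFS)
        assert call.subfamily == "unclassified"

    def test_support_at_threshold_is_accepted(self):
        tree = parse_newick("(((Q,R5)0.5,R2)1.0,(R4a,R4b)1.0);")
        call = assign_subfamily(tree, "Q", self.REFS, min_support=0.5)
        assert call.subfamily == "V"
        assert call.support == pytest.approx(0.5)

    def test_below_threshold_clades_skipped(self):
        # the small clade is weak; the next one up mixes subfamilies
        tree = parse_newick("(((Q,R5)0.4,R2)0.4,(R4a,R4b)1.0);")
        call = assign_subfamily(tree, "Q", self.REFS, min_support=0.5)
        assert call.subfamily == "unclassified"

    def test_reference_query_returns_its_mapping(self):
        tree = parse_newick("(((R4a,R4b)0.3,R2)0.3,(R5,X));")
        call = assign_subfamily(tree, "R4a", self.REFS, min_support=0.9)
        assert call.subfamily == "IV"
        assert call.support == 1.0

    def test_reference_leaf_with_zero_min_support(self):
        tree = parse_newick("(((Q,R4a)0.2,R4b)0.2,(R2,R5));")
        call = assign_subfamily(tree, "Q", self.REFS, min_support=0.0)
        assert call.subfamily == "IV"


class TestNjTree:
    def test_three_taxa_closed_form(self):
        labels = ["A", "B", "C"]
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(labels, d)
        # branch lengths solve the three-point equations: a=1, b=2, c=3
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree._dtree.leaf_node_iter()
        }
        assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(2.0), "C": pytest.approx(3.0)}

    def test_recovers_additive_four_taxon_tree(self):
        source = parse_newick("((A:1,B:2):1,(C:1,D:3));")
        labels, d = patristic_matrix(source)
        assert rf_distance(source, nj_tree(labels, d)) == 0

    def test_equidistant_matrix_gives_nonnegative_lengths(self):
        labels = ["A", "B", "C", "D", "E"]
        d = np.ones((5, 5)) - np.eye(5)
        tree = nj_tree(labels, d)
        for node in tree._dtree.preorder_node_iter():
            if node.edge.length is not None:
                assert node.edge.length >= 0

    def test_negative_distance_is_error(self):
        d = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(InputError, match="negative"):
            nj_tree(["A", "B"], d)

    def test_recovers_random_additive_topologies(self, rng):
        for _ in range(20):
            source = random_tree(8, rng)
            labels, d = patristic_matrix(source)
            assert rf_distance(source, nj_tree(labels, d)) == 0


class TestPoissonDistance:
    def test_identical_sequences_have_zero_distance(self):
        from bcescan.io import SequenceRecord
        from bcescan.phylo import poisson_distance_matrix

        recs = [
            SequenceRecord("a", "MKTAYIAKQRQISFVK"),
            SequenceRecord("b", "MKTAYIAKQRQISFVK"),
            SequenceRecord("c", "MKTAYIAKQRQISFWK"),
        ]
        labels, d = poisson_distance_matrix(recs)
        i, j = labels.index("a"), labels.index("b")
        assert d[i, j] == 0.0
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0.0)
        k = labels.index("c")
        assert d[i, k] > 0.0


class TestRfDistance:
    def test_identical_trees(self):
        t = parse_newick("((A,B),(C,D),E);")
        assert rf_distance(t, parse_newick("((A,B),(C,D),E);")) == 0

    def test_textbook_four_taxon_case(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,C),(B,D));")
        assert rf_distance(t1, t2) == 2

    def test_pruning_to_shared_leaves(self, rng):
        big = random_tree(10, rng)
        keep = sorted(big.leaf_labels())[:6]
        small = parse_newick(big.to_newick())
        small._dtree.retain_taxa_with_labels(keep)
        assert rf_distance(big, small) == 0

    def test_too_few_shared_leaves_is_error(self):
        t1 = parse_newick("((A,B),(C,X));")
        t2 = parse_newick("((A,B),(Y,Z));")
        with pytest.raises(InputError, match="shared"):
            rf_distance(t1, t2)

    def test_metric_properties_spot_check(self, rng):
        trees = [random_tree(8, rng, labels=[f"L{i}" for i in range(8)]) for _ in range(3)]
        a, b, c = trees
        assert rf_distance(a, b) == rf_distance(b, a)
        assert rf_distance(a, a) == 0
        assert rf_distance(a, c) <= rf_distance(a, b) + rf_distance(b, c)


def _cluster_for_queries(q, genome="G1"):
    members = []
    for i, comp in enumerate(("RR", "HK", "NBD", "MSD")):
        members.append(
            (
                GeneFeature(
                    gene_id=f"Q{q}_{comp}", genome_id=genome, contig="c1",
                    start=100 * i + 1, end=100 * i + 50, strand="+", rank=i,
                ),
                comp,
            )
        )
    return ModuleCluster(genome_id=genome, contig="c1", members=members)


class TestConcordance:
    def test_planted_concordant_clusters_agree(self):
        cfg = SimConfig(seed=3, n_queries=12)
        trees, truth = plant_reference_trees(cfg)
        refs = {c: reference_map_for(c, cfg) for c in trees}
        clusters = [_cluster_for_queries(q) for q in truth]
        report = concordance(clusters, trees, refs)
        assert report.agreement_fraction == 1.0
        for cc in report.per_cluster:
            assert cc.agree is True

    def test_disagreeing_cluster_detected(self):
        cfg = SimConfig(seed=3, n_queries=12)
        trees, truth = plant_reference_trees(cfg)
        refs = {c: reference_map_for(c, cfg) for c in trees}
        # pair query 0's RR/HK/NBD with query 1's MSD (different subfamily)
        cluster = _cluster_for_queries(0)
        feature, _ = cluster.members[3]
        feature.gene_id = "Q1_MSD"
        report = concordance([cluster], trees, refs)
        assert report.per_cluster[0].agree is False
        assert report.agreement_fraction == 0.0

    def test_member_missing_from_tree_is_unclassified(self, caplog):
        import logging

        cfg = SimConfig(seed=3, n_queries=12)
        trees, truth = plant_reference_trees(cfg)
        refs = {c: reference_map_for(c, cfg) for c in trees}
        cluster = _cluster_for_queries(0)
        cluster.members[0][0].gene_id = "not_in_tree"
        with caplog.at_level(logging.WARNING):
            report = concordance([cluster], trees, refs)
        call = report.per_cluster[0].calls["RR"]
        assert call.subfamily == "unclassified"
        assert report.per_cluster[0].agree is True  # remaining three agree
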