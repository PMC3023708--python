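from bcescan.clustering import (
    build_clusters,
    classify_cluster,
    clusters_to_frame,
    repertoire,
)
from bcescan.homology import ComponentCall
from bcescan.io import GeneFeature


def make_genome(spec, genome="G1", contig="c1"):
    """spec: list of (component-or-None, product) in gene order; returns
    (features, calls)."""
    features, calls = [], []
    for i, (component, product) in enumerate(spec):
        gid = f"{genome}_g{i}"
        features.append(
            GeneFeature(
                gene_id=gid, genome_id=genome, contig=contig,
                start=100 * i + 1, end=100 * i + 50, strand="+",
                rank=i, product=product,
            )
        )
        calls.append(
            ComponentCall(gid, component or "none", "seed", 100.0, 0.5)
        )
    return features, calls


def brute_force_clusters(component_ranks, max_gap):
    """Independent exhaustive gap scan over the ranks of component genes."""
    groups, current = [], []
    for r in sorted(component_ranks):
        if current and r - current[-1] - 1 > max_gap:
            groups.append(current)
            current = []
        current.append(r)
    if current:
        groups.append(current)
    return groups


class TestBuildClusters:
    def test_contiguous_module_is_one_cluster(self):
        feats, calls = make_genome([("RR", ""), ("HK", ""), ("NBD", ""), ("MSD", "")])
        clusters = build_clusters(feats, calls)
        assert len(clusters) == 1
        assert clusters[0].intervening_counts == [0, 0, 0]
        assert [c for _f, c in clusters[0].members] == ["RR", "HK", "NBD", "MSD"]

    def test_gap_above_max_splits(self):
        spec = [("RR", ""), ("HK", "")] + [(None, "")] * 5 + [("NBD", ""), ("MSD", "")]
        feats, calls = make_genome(spec)
        clusters = build_clusters(feats, calls, max_gap=3)
        assert len(clusters) == 2
        ranks = [f.rank for f in feats if f.gene_id in {c.seq_id for c in calls if c.component != "none"}]
        component_ranks = [f.rank for (f, _c) in clusters[0].members] + [
            f.rank for (f, _c) in clusters[1].members
        ]
        assert brute_force_clusters(component_ranks, 3) == [
            [f.rank for f, _c in cl.members] for cl in clusters
        ]

    def test_lone_gene_is_singleton_cluster(self):
        feats, calls = make_genome([(None, ""), ("MSD", ""), (None, "")])
        clusters = build_clusters(feats, calls)
        assert len(clusters) == 1
        assert clusters[0].member_ids == ("G1_g1",)

    def test_matches_exhaustive_scan_on_random_layouts(self, rng):
        for trial in range(50):
            n = 30
            spec = [
                (rng.choice(["RR", "HK", "NBD", "MSD", None, None, None]), "")
                for _ in range(n)
            ]
            max_gap = int(rng.integers(0, 5))
            feats, calls = make_genome(spec)
            clusters = build_clusters(feats, calls, max_gap=max_gap)
            component_ranks = [
                i for i, (c, _p) in enumerate(spec) if c is not None
            ]
            expected = brute_force_clusters(component_ranks, max_gap)
            got = [[f.rank for f, _c in cl.members] for cl in clusters]
            assert got == expected

    def test_partition_of_called_genes(self, rng):
        spec = [
            (rng.choice(["RR", "HK", "NBD", "MSD", None]), "") for _ in range(40)
        ]
        feats, calls = make_genome(spec)
        clusters = build_clusters(feats, calls, max_gap=2)
        seen = [gid for cl in clusters for gid in cl.member_ids]
        called = [c.seq_id for c in calls if c.component != "none"]
        assert sorted(seen) == sorted(called)

    def test_increasing_max_gap_never_increases_cluster_count(self, rng):
        spec = [
            (rng.choice(["RR", "HK", "NBD", "MSD", None, None]), "")
            for _ in range(40)
        ]
        feats, calls = make_genome(spec)
        counts = [len(build_clusters(feats, calls, max_gap=g)) for g in range(6)]
        assert counts == sorted(counts, reverse=True)

    def test_call_without_feature_ignored_with_warning(self, caplog):
        import logging

        feats, calls = make_genome([("RR", "")])
        calls.append(ComponentCall("ghost", "MSD", "seed", 10.0, 0.3))
        with caplog.at_level(logging.WARNING):
            clusters = build_clusters(feats, calls)
        assert len(clusters) == 1
        assert "ghost" in caplog.text


class TestClassifyCluster:
    def _classified(self, spec, **kwargs):
        feats, calls = make_genome(spec)
        clusters = build_clusters(feats, calls)
        return [classify_cluster(c, feats, calls, **kwargs) for c in clusters]

    def test_complete(self):
        (c,) = self._classified([("RR", ""), ("HK", ""), ("NBD", ""), ("MSD", "")])
        assert c.cluster_class == "complete"

    def test_complete_with_duplicated_msd(self):
        (c,) = self._classified(
            [("RR", ""), ("HK", ""), ("NBD", ""), ("MSD", ""), ("MSD", ""), ("MSD", "")]
        )
        assert c.cluster_class == "complete"
        assert c.composition["MSD"] == 3

    def test_transporter_only(self):
        (c,) = self._classified(
            [(None, "enolase"), ("NBD", ""), ("MSD", ""), (None, "enolase")]
        )
        assert c.cluster_class == "transporter_only"

    def test_foreign_regulator_from_product_text(self):
        (c,) = self._classified(
            [(None, "sensor histidine kinase"), ("NBD", ""), ("MSD", "")]
        )
        assert c.cluster_class == "foreign_regulator"

    def test_partial_when_cognate_regulator_nearby(self):
        # an RR call 4 genes away: same contig, outside the cluster, inside scan
        spec = [("RR", "")] + [(None, "")] * 5 + [("NBD", ""), ("MSD", "")]
        feats, calls = make_genome(spec)
        clusters = build_clusters(feats, calls, max_gap=3)
        transporter = [c for c in clusters if "NBD" in c.composition][0]
        classify_cluster(transporter, feats, calls, nearby_regulator_scan=6)
        assert transporter.cluster_class == "partial"

    def test_partial_when_one_component_missing(self):
        (c,) = self._classified([("RR", ""), ("HK", ""), ("NBD", "")])
        assert c.cluster_class == "partial"


class TestRepertoire:
    def test_counts_per_genome(self):
        feats1, calls1 = make_genome(
            [("RR", ""), ("HK", ""), ("NBD", ""), ("MSD", "")], genome="G1"
        )
        feats2, calls2 = make_genome([("NBD", ""), ("MSD", "")], genome="G2")
        feats, calls = feats1 + feats2, calls1 + calls2
        clusters = build_clusters(feats, calls)
        for c in clusters:
            classify_cluster(c, feats, calls)
        rows = {r.genome_id: r for r in repertoire(clusters, ["G1", "G2", "G3"])}
        assert rows["G1"].complete == 1
        assert rows["G2"].transporter_only == 1
        assert rows["G3"].clusters == 0

    def test_class_counts_sum_to_clusters(self):
        feats, calls = make_genome(
            [("RR", ""), ("HK", ""), ("NBD", ""), ("MSD", "")] + [(None, "")] * 5
            + [("MSD", "")]
        )
        clusters = build_clusters(feats, calls)
        for c in clusters:
            classify_cluster(c, feats, calls)
        (row,) = repertoire(clusters)
        assert (
            row.complete + row.transporter_only + row.partial + row.foreign_regulator
            == row.clusters
        )

    def test_cluster_frame_has_one_row_per_member(self):
        feats, calls = make_genome([("RR", ""), ("HK", ""), ("NBD", ""), ("MSD", "")])
        clusters = build_clusters(feats, calls)
        df = clusters_to_frame(clusters)
        assert len(df) == 4
        assert df.cluster_id.nunique() == 1
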