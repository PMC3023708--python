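"""Chromosomal clustering of component-called genes.

Genes whose products were typed RR/HK/NBD/MSD are grouped into clusters per
contig: consecutive component genes separated by at most ``max_gap``
intervening non-component genes belong to the same cluster.  Strand is
recorded but never splits a cluster — the modules are defined by physical
proximity, not co-orientation.  Each cluster is then classed as complete
(≥1 of each component), transporter_only (NBD/MSD with no cognate regulator
nearby), foreign_regulator (NBD/MSD next to a non-homologous regulator pair,
the salXY pattern), or partial.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .homology import ComponentCall
from .io import GeneFeature

logger = logging.getLogger(__name__)

CLUSTER_CLASSES = ("complete", "transporter_only", "partial", "foreign_regulator")

#: product-text signature of a regulator/kinase gene that was not component-called
REGULATOR_PRODUCT_RE = re.compile(
    r"response regulator|histidine kinase|sensor", re.IGNORECASE
)


@dataclass
class ModuleCluster:
    genome_id: str
    contig: str
    members: list[tuple[GeneFeature, str]]  # (feature, component), ordered by rank
    intervening_counts: list[int] = field(default_factory=list)
    cluster_class: str = ""

    @property
    def composition(self) -> Counter:
        return Counter(comp for _f, comp in self.members)

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(f.gene_id for f, _c in self.members)

    @property
    def pseudo_members(self) -> int:
        return sum(1 for f, _c in self.members if f.pseudo)


@dataclass
class RepertoireRow:
    genome_id: str
    clusters: int
    complete: int
    transporter_only: int
    partial: int
    foreign_regulator: int
    duplicated_msd: bool
    duplicated_nbd: bool
    pseudo_members: int


def build_clusters(
    features: list[GeneFeature],
    calls: list[ComponentCall],
    max_gap: int = 3,
) -> list[ModuleCluster]:
    """Group component-called genes into per-contig clusters.

    A cluster is a maximal run of component genes in rank order in which
    consecutive component genes are separated by at most ``max_gap``
    non-component genes.  Singletons are allowed.  Calls for ids absent from
    the feature table are ignored with a warning.
    """
    component_of = {c.seq_id: c.component for c in calls if c.component != "none"}
    feature_ids = {f.gene_id for f in features}
    for seq_id in sorted(set(component_of) - feature_ids):
        logger.warning("component call for %s has no gene feature; ignored", seq_id)

    by_contig: dict[tuple[str, str], list[GeneFeature]] = {}
    for f in features:
        by_contig.setdefault((f.genome_id, f.contig), []).append(f)

    clusters: list[ModuleCluster] = []
    for (genome_id, contig), feats in sorted(by_contig.items()):
        feats = sorted(feats, key=lambda f: f.rank)
        component_feats = [f for f in feats if f.gene_id in component_of]
        if not component_feats:
            continue
        run: list[GeneFeature] = [component_feats[0]]
        gaps: list[int] = []
        for prev, cur in zip(component_feats, component_feats[1:]):
            gap = cur.rank - prev.rank - 1
            if gap <= max_gap:
                run.append(cur)
                gaps.append(gap)
            else:
                clusters.append(
                    ModuleCluster(
                        genome_id=genome_id,
                        contig=contig,
                        members=[(f, component_of[f.gene_id]) for f in run],
                        intervening_counts=gaps,
                    )
                )
                run, gaps = [cur], []
        clusters.append(
            ModuleCluster(
                genome_id=genome_id,
                contig=contig,
                members=[(f, component_of[f.gene_id]) for f in run],
                intervening_counts=gaps,
            )
        )
    return clusters


def classify_cluster(
    cluster: ModuleCluster,
    features: list[GeneFeature],
    calls: list[ComponentCall],
    nearby_regulator_scan: int = 5,
) -> ModuleCluster:
    """Set ``cluster_class`` on a cluster.

    complete: at least one copy of each of RR, HK, NBD, MSD.
    transporter_only: only NBD/MSD, and no component-called RR/HK within
    ``nearby_regulator_scan`` genes of the cluster ends.
    foreign_regulator: only NBD/MSD, no component-called RR/HK nearby, but a
    gene whose product text matches a regulator/kinase signature lies within
    the scan window.
    partial: anything else short of complete.
    """
    comp = cluster.composition
    if all(comp.get(c, 0) >= 1 for c in ("RR", "HK", "NBD", "MSD")):
        cluster.cluster_class = "complete"
        return cluster
    transporter_only_composition = set(comp) <= {"NBD", "MSD"} and comp
    if not transporter_only_composition:
        cluster.cluster_class = "partial"
        return cluster

    component_of = {c.seq_id: c.component for c in calls if c.component != "none"}
    contig_feats = sorted(
        (
            f
            for f in features
            if f.genome_id == cluster.genome_id and f.contig == cluster.contig
        ),
        key=lambda f: f.rank,
    )
    ranks = [f.rank for f, _c in cluster.members]
    lo, hi = min(ranks) - nearby_regulator_scan, max(ranks) + nearby_regulator_scan
    member_ids = set(cluster.member_ids)
    nearby = [
        f
        for f in contig_feats
        if lo <= f.rank <= hi and f.gene_id not in member_ids
    ]
    cognate_nearby = any(
        component_of.get(f.gene_id) in ("RR", "HK") for f in nearby
    )
    foreign_nearby = any(
        f.gene_id not in component_of and REGULATOR_PRODUCT_RE.search(f.product or "")
        for f in nearby
    )
    if cognate_nearby:
        cluster.cluster_class = "partial"
    elif foreign_nearby:
        cluster.cluster_class = "foreign_regulator"
    else:
        cluster.cluster_class = "transporter_only"
    return cluster


def repertoire(
    clusters: list[ModuleCluster],
    genome_ids: list[str] | None = None,
) -> list[RepertoireRow]:
    """One row per genome summarizing its Bce-like cluster repertoire.

    ``genome_ids`` may list genomes with zero clusters so they appear as
    all-zero rows (genomes carrying no components at all).
    """
    by_genome: dict[str, list[ModuleCluster]] = {}
    for c in clusters:
        by_genome.setdefault(c.genome_id, []).append(c)
    all_ids = sorted(set(by_genome) | set(genome_ids or []))
    rows = []
    for gid in all_ids:
        cs = by_genome.get(gid, [])
        class_counts = Counter(c.cluster_class for c in cs)
        rows.append(
            RepertoireRow(
                genome_id=gid,
                clusters=len(cs),
                complete=class_counts.get("complete", 0),
                transporter_only=class_counts.get("transporter_only", 0),
                partial=class_counts.get("partial", 0),
                foreign_regulator=class_counts.get("foreign_regulator", 0),
                duplicated_msd=any(c.composition.get("MSD", 0) > 1 for c in cs),
                duplicated_nbd=any(c.composition.get("NBD", 0) > 1 for c in cs),
                pseudo_members=sum(c.pseudo_members for c in cs),
            )
        )
    return rows


def clusters_to_frame(clusters: list[ModuleCluster]) -> pd.DataFrame:
    """Long-format cluster report: one member per row with its cluster id."""
    rows = []
    for i, c in enumerate(clusters):
        for (f, comp) in c.members:
            rows.append(
                {
                    "cluster_id": f"{c.genome_id}:{c.contig}:{i}",
                    "genome": c.genome_id,
                    "contig": c.contig,
                    "gene_id": f.gene_id,
                    "component": comp,
                    "rank": f.rank,
                    "strand": f.strand,
                    "pseudo": f.pseudo,
                    "cluster_class": c.cluster_class,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "genome", "contig", "gene_id", "component",
            "rank", "strand", "pseudo", "cluster_class",
        ],
    )


def repertoire_to_frame(rows: list[RepertoireRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])
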