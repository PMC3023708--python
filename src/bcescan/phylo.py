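"""Tree-based subfamily classification and congruence.

Bce-like modules fall into six phylogenetic subfamilies (I–VI); a query
protein is assigned by finding the smallest supported clade that contains
it together with reference leaves of a single subfamily.  Clade search uses
unrooted bipartition semantics — imported trees have arbitrary rooting, so
the root is never trusted.  Node supports are posterior probabilities or
bootstrap values normalized to [0, 1] on read.  A neighbor-joining builder
is provided as a fallback for when no published tree is available, and
Robinson–Foulds distance quantifies cross-component tree congruence.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .errors import InputError
from .clustering import ModuleCluster
from .homology import sw_align
from .io import SequenceRecord

logger = logging.getLogger(__name__)

SUBFAMILIES = ("I", "II", "III", "IV", "V", "VI")


class Tree:
    """An (un)rooted phylogeny with unique leaf labels and normalized
    supports.  Thin wrapper around a dendropy tree."""

    def __init__(self, dtree: dendropy.Tree, rooted: bool = False):
        self._dtree = dtree
        self.rooted = rooted
        self._normalize_supports()
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise InputError(f"duplicate leaf labels: {', '.join(dupes)}")

    @classmethod
    def from_newick(cls, text: str, rooted: bool = False) -> "Tree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
                rooting="force-unrooted" if not rooted else "force-rooted",
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise InputError(f"newick parse error: {exc}") from exc
        return cls(dtree, rooted=rooted)

    def _normalize_supports(self) -> None:
        for node in self._dtree.preorder_node_iter():
            support = None
            if not node.is_leaf() and node.label is not None:
                try:
                    support = float(node.label)
                except ValueError:
                    support = None
            if support is not None and support > 1.0:
                support = support / 100.0
            if support is not None and not (0.0 <= support <= 1.0):
                raise InputError(f"support {support} outside [0,1] after normalization")
            node.support = support

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._dtree.leaf_node_iter()]

    def to_newick(self) -> str:
        out = self._dtree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
        return out

    def bipartitions(self) -> list[tuple[frozenset, float]]:
        """All non-trivial bipartitions as (one side's leaf set, support).

        Each internal edge yields the leaf set below it; the complement is
        implicit.  Unannotated edges count as fully supported (1.0).
        """
        all_leaves = frozenset(self.leaf_labels())
        out = []
        seen: set[frozenset] = set()
        for node in self._dtree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if side == all_leaves or len(side) == len(all_leaves) - 1:
                continue  # trivial under unrooted semantics
            canonical = min(side, all_leaves - side, key=lambda s: (len(s), sorted(s)))
            if canonical in seen:
                continue
            seen.add(canonical)
            out.append((side, node.support if node.support is not None else 1.0))
        return out


@dataclass
class SubfamilyCall:
    query: str
    subfamily: str  # "I".."VI" or "unclassified"
    support: float
    n_refs_in_clade: int


@dataclass
class ClusterConcordance:
    cluster_id: str
    calls: dict[str, SubfamilyCall]  # component -> call
    agree: bool | None  # None when <2 classified components


@dataclass
class ConcordanceReport:
    per_cluster: list[ClusterConcordance]
    agreement_fraction: float


def load_reference_map(path: str | Path) -> dict[str, str]:
    """Read a leaf_label<TAB>subfamily map."""
    refs: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise InputError(f"{path}:{lineno}: expected 2 tab-separated columns")
        label, subfamily = parts
        if subfamily not in SUBFAMILIES:
            raise InputError(f"{path}:{lineno}: unknown subfamily {subfamily!r}")
        refs[label] = subfamily
    return refs


def default_reference_map(component: str) -> dict[str, str]:
    """Reference accessions anchoring subfamilies, per component.

    Only accessions that can be tied unambiguously to a subfamily are
    shipped: the S. mutans BceRSAB operon (II), the B. subtilis Bce module
    and S. aureus VraFG/GraRS (IV), the L. monocytogenes AnrAB and
    S. pyogenes SalXY transporters (V).  The map is deliberately sparse and
    user-extensible; subfamily VI anchors exist only for transporter
    components (no regulator or kinase belongs to it).
    """
    maps = {
        "RR": {"NP_721401": "II", "O34951": "IV", "YP_416102": "IV"},
        "HK": {"NP_721402": "II", "O35044": "IV", "YP_416103": "IV"},
        "NBD": {
            "NP_721403": "II",
            "O34697": "IV",
            "YP_416104": "IV",
            "NP_465638": "V",
            "NP_269896": "V",
        },
        "MSD": {
            "NP_721404": "II",
            "O34741": "IV",
            "YP_416105": "IV",
            "NP_465639": "V",
            "NP_269895": "V",
        },
    }
    if component not in maps:
        raise InputError(f"unknown component {component!r}")
    return maps[component]


def is_monophyletic(tree: Tree, leaves: set[str]) -> tuple[bool, float]:
    """Whether some edge bipartition isolates exactly ``leaves``.

    Returns (verdict, support); support is the isolating edge's, 1.0 when
    the edge is unannotated or the query set is trivial (a single leaf or
    all leaves).
    """
    all_leaves = set(tree.leaf_labels())
    unknown = set(leaves) - all_leaves
    if unknown:
        raise InputError(f"labels not in tree: {', '.join(sorted(unknown))}")
    query = frozenset(leaves)
    if len(query) in (1, len(all_leaves)):
        return True, 1.0
    complement = frozenset(all_leaves) - query
    if len(complement) == 1:
        return True, 1.0  # pendant bipartition, trivially present
    for side, support in tree.bipartitions():
        if side == query or side == complement:
            return True, support
    return False, 0.0


def assign_subfamily(
    tree: Tree,
    query: str,
    refs: dict[str, str],
    min_support: float = 0.5,
) -> SubfamilyCall:
    """Place ``query`` into a subfamily from reference-anchored clades.

    The candidate clades are the sides of internal-edge bipartitions that
    contain the query, at least one reference, and support ≥ ``min_support``
    (unannotated edges count as 1.0).  The smallest such clade decides: if
    all its references share one subfamily the query joins it, otherwise —
    or when no clade qualifies — the query is unclassified.  A query that is
    itself a reference returns its own mapping with support 1.0.
    """
    leaves = set(tree.leaf_labels())
    if query not in leaves:
        raise InputError(f"query {query!r} not in tree")
    refs_in_tree = {label: fam for label, fam in refs.items() if label in leaves}
    if query in refs_in_tree:
        return SubfamilyCall(query, refs_in_tree[query], 1.0, 1)
    if not refs_in_tree:
        return SubfamilyCall(query, "unclassified", 0.0, 0)

    all_leaves = frozenset(leaves)
    best: tuple[int, tuple, frozenset, float] | None = None
    for side, support in tree.bipartitions():
        clade = side if query in side else all_leaves - side
        n_refs = sum(1 for r in refs_in_tree if r in clade)
        if n_refs == 0 or support < min_support:
            continue
        key = (len(clade), tuple(sorted(clade)))
        if best is None or key < best[:2]:
            best = (len(clade), tuple(sorted(clade)), clade, support)
    if best is None:
        return SubfamilyCall(query, "unclassified", 0.0, 0)
    clade, support = best[2], best[3]
    clade_fams = {fam for label, fam in refs_in_tree.items() if label in clade}
    n_refs = sum(1 for label in refs_in_tree if label in clade)
    if len(clade_fams) == 1:
        return SubfamilyCall(query, clade_fams.pop(), support, n_refs)
    return SubfamilyCall(query, "unclassified", support, n_refs)


def nj_tree(labels: list[str], d: np.ndarray) -> Tree:
    """Classical neighbor joining with a deterministic tie-break.

    ``d`` is a symmetric matrix with zero diagonal over ``labels``; negative
    entries are a hard error.  When several pairs minimize the Q criterion,
    the lexicographically smallest label pair is joined.  Estimated branch
    lengths are clipped at zero.
    """
    d = np.asarray(d, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise InputError("distance matrix shape does not match labels")
    if (d < 0).any():
        raise InputError("negative distances are not allowed")
    if not np.allclose(d, d.T):
        raise InputError("distance matrix is not symmetric")

    taxon_namespace = dendropy.TaxonNamespace(labels)
    nodes = []
    for label in labels:
        node = dendropy.Node(taxon=taxon_namespace.get_taxon(label))
        node.nj_label = label  # lexicographic tie-break key
        nodes.append(node)
    active = list(range(n))
    dist = d.copy()

    while len(active) > 3:
        m = len(active)
        sums = {i: sum(dist[i, j] for j in active if j != i) for i in active}
        best_pair = None
        best_q = math.inf
        for i, j in itertools.combinations(active, 2):
            q = (m - 2) * dist[i, j] - sums[i] - sums[j]
            pair_key = tuple(sorted((nodes[i].nj_label, nodes[j].nj_label)))
            if q < best_q - 1e-12 or (
                abs(q - best_q) <= 1e-12
                and best_pair is not None
                and pair_key < best_pair[2]
            ):
                best_q = q
                best_pair = (i, j, pair_key)
        i, j, _key = best_pair
        li = 0.5 * dist[i, j] + (sums[i] - sums[j]) / (2 * (m - 2))
        lj = dist[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.nj_label = min(nodes[i].nj_label, nodes[j].nj_label)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        new_index = len(nodes)
        nodes.append(parent)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            dist[new_index, k] = dist[k, new_index] = max(
                0.5 * (dist[i, k] + dist[j, k] - dist[i, j]), 0.0
            )
        active = [k for k in active if k not in (i, j)] + [new_index]

    root = dendropy.Node()
    if len(active) == 3:
        i, j, k = active
        li = 0.5 * (dist[i, j] + dist[i, k] - dist[j, k])
        lj = 0.5 * (dist[i, j] + dist[j, k] - dist[i, k])
        lk = 0.5 * (dist[i, k] + dist[j, k] - dist[i, j])
        for idx, ln in ((i, li), (j, lj), (k, lk)):
            root.add_child(nodes[idx])
            nodes[idx].edge.length = max(ln, 0.0)
    elif len(active) == 2:
        i, j = active
        for idx, ln in ((i, dist[i, j] / 2), (j, dist[i, j] / 2)):
            root.add_child(nodes[idx])
            nodes[idx].edge.length = max(ln, 0.0)
    else:
        root = nodes[active[0]]
    dtree = dendropy.Tree(taxon_namespace=taxon_namespace, seed_node=root)
    dtree.is_rooted = False
    return Tree(dtree, rooted=False)


def _pruned_newick(tree: Tree, keep: set[str]) -> str:
    clone = dendropy.Tree(tree._dtree)
    clone.retain_taxa_with_labels(sorted(keep))
    return clone.as_string(schema="newick", suppress_rooting=True)


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson–Foulds distance on the shared leaf set.

    Both trees are pruned to their shared leaves first; fewer than four
    shared leaves is a hard error (no informative bipartitions exist).
    """
    shared = set(t1.leaf_labels()) & set(t2.leaf_labels())
    if len(shared) < 4:
        raise InputError(f"only {len(shared)} shared leaves; need at least 4")
    tns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(
        data=_pruned_newick(t1, shared), schema="newick",
        taxon_namespace=tns, preserve_underscores=True,
    )
    d2 = dendropy.Tree.get(
        data=_pruned_newick(t2, shared), schema="newick",
        taxon_namespace=tns, preserve_underscores=True,
    )
    d1.is_rooted = d2.is_rooted = False
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(d1, d2))


def poisson_distance_matrix(records: list[SequenceRecord]) -> tuple[list[str], np.ndarray]:
    """Pairwise Poisson-corrected distances −ln(1−p) from local alignments.

    p is the proportion of mismatched aligned (gap-free) residue pairs in
    the Smith–Waterman alignment of each pair.  Used to feed the NJ
    fallback when no published tree exists.
    """
    labels = [r.id for r in records]
    n = len(records)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        res = sw_align(records[i], records[j])
        p = 1.0 - res.identity if res.aligned_pairs else 1.0
        p = min(p, 0.95)  # cap to keep the correction finite
        d[i, j] = d[j, i] = -math.log(1.0 - p)
    return labels, d


def concordance(
    clusters: list[ModuleCluster],
    trees: dict[str, Tree],
    refs: dict[str, dict[str, str]],
    min_support: float = 0.5,
) -> ConcordanceReport:
    """Do the components of each cluster land in the same subfamily?

    Each member of each cluster is placed on its component's tree; a
    cluster agrees when all its classified (non-unclassified) components
    share one subfamily.  Clusters with fewer than two classified
    components are excluded from the global agreement fraction.  Members
    missing from their tree are reported unclassified with a warning.
    """
    per_cluster: list[ClusterConcordance] = []
    agreeing = considered = 0
    for idx, cluster in enumerate(clusters):
        calls: dict[str, SubfamilyCall] = {}
        for feature, component in cluster.members:
            if component not in trees:
                continue
            tree = trees[component]
            if feature.gene_id not in set(tree.leaf_labels()):
                logger.warning(
                    "cluster member %s absent from %s tree; unclassified",
                    feature.gene_id,
                    component,
                )
                calls[component] = SubfamilyCall(feature.gene_id, "unclassified", 0.0, 0)
                continue
            calls[component] = assign_subfamily(
                tree, feature.gene_id, refs.get(component, {}), min_support
            )
        classified = [c.subfamily for c in calls.values() if c.subfamily != "unclassified"]
        agree: bool | None
        if len(classified) < 2:
            agree = None
        else:
            agree = len(set(classified)) == 1
            considered += 1
            agreeing += int(agree)
        cluster_id = f"{cluster.genome_id}:{cluster.contig}:{idx}"
        per_cluster.append(ClusterConcordance(cluster_id, calls, agree))
    fraction = agreeing / considered if considered else float("nan")
    return ConcordanceReport(per_cluster=per_cluster, agreement_fraction=fraction)
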