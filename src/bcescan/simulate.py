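"""Seeded synthetic datasets with known ground truth for every pipeline stage.

The generator emits genomes as ordered gene lists with planted four-component
Bce-like modules (RR + HK + NBD + MSD, with realistic intervening genes),
decoys each violating exactly one detection rule, topology annotations,
protein families evolved down trees with per-region substitution rates, and
reference trees with six labelled subfamily clades.  Everything is
deterministic under the configured seed, and emitted files use exactly the
formats the readers consume.

Substitution model: along a branch of length b a site is redrawn uniformly
from the 20-residue alphabet with probability 1 − exp(−rate·b) (a
Jukes–Cantor-style randomization, kept in one function so an empirical
matrix could replace it).  Indels are off by default so the true alignment
is the gap-free site matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InputError
from .io import (
    GeneFeature,
    MSA,
    SequenceRecord,
    write_fasta,
    write_features,
    write_tmhmm,
)
from .phylo import Tree
from .topology import Topology

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residue pools used to give I/O vs TM segments realistic hydropathy
POLAR_POOL = "ADEGHKNPQRSTY"
HYDROPHOBIC_POOL = "AFILMVW"

DECOY_KINDS = (
    "wrong_tm_count",
    "loop_too_short",
    "loop_too_long",
    "missing_component",
    "shuffled_order",
)

#: internal constant seed for the synthetic stand-in seed proteins, so the
#: same seed sequences are produced regardless of the dataset seed
_SEED_PROTEIN_RNG_SEED = 20110119


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    ``total_modules`` complete modules are spread as evenly as possible over
    ``n_genomes`` genomes; ``decoy_counts`` gives the number of decoys per
    kind, distributed round-robin.  ``region_rates`` are substitution rates
    per unit branch length for transmembrane, intracellular, short outside
    and large-loop (O4) regions.  ``divergence`` is the per-site redraw
    probability applied to seed copies planted in genomes.
    """

    seed: int = 0
    n_genomes: int = 20
    total_modules: int = 50
    decoy_counts: dict = field(
        default_factory=lambda: {kind: 0 for kind in DECOY_KINDS}
    )
    divergence: float = 0.3
    region_rates: dict = field(
        default_factory=lambda: {"TM": 0.2, "I": 0.5, "O_short": 0.5, "O4": 1.5}
    )
    max_intervening_planted: int = 2
    background_run: int = 5  # background genes between planted entities
    n_refs_per_subfamily: int = 2
    n_queries: int = 60
    ref_clade_support: float = 1.0
    tree_taxa: int = 8
    birth_rate: float = 1.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.decoy_counts.values()):
            raise InputError("decoy counts must be non-negative")
        unknown = set(self.decoy_counts) - set(DECOY_KINDS)
        if unknown:
            raise InputError(f"unknown decoy kinds: {sorted(unknown)}")
        if not 0.0 <= self.divergence <= 1.0:
            raise InputError("divergence must be a probability")
        if any(r < 0 for r in self.region_rates.values()):
            raise InputError("region rates must be non-negative")


@dataclass
class PlantedModule:
    genome_id: str
    members: dict  # component -> gene_id
    intervening_counts: list[int]
    subfamily: str


@dataclass
class PlantedDecoy:
    genome_id: str
    kind: str
    members: dict  # component -> gene_id
    expected_failure: str  # architecture failure reason, or a cluster-level note


@dataclass
class TruthTable:
    modules: list[PlantedModule]
    decoys: list[PlantedDecoy]
    component_of: dict  # gene_id -> true component ("none" for background)

    def complete_member_sets(self) -> set[frozenset]:
        return {frozenset(m.members.values()) for m in self.modules}


@dataclass
class SyntheticDataset:
    config: SimConfig
    features: list[GeneFeature]
    proteome: list[SequenceRecord]
    topologies: dict  # gene_id -> Topology
    seeds: dict  # component -> SequenceRecord (header carries component= tag)
    truth: TruthTable

    def write_bundle(self, outdir: str | Path) -> dict:
        """Write proteome.fasta, features.tsv, topology.tmhmm, seeds.fasta
        and truth.tsv; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteome": outdir / "proteome.fasta",
            "features": outdir / "features.tsv",
            "topology": outdir / "topology.tmhmm",
            "seeds": outdir / "seeds.fasta",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(self.proteome, paths["proteome"])
        write_features(self.features, paths["features"])
        write_tmhmm(self.topologies, paths["topology"])
        seed_records = [
            SequenceRecord(
                id=rec.id, residues=rec.residues, description=f"component={comp}"
            )
            for comp, rec in self.seeds.items()
        ]
        write_fasta(seed_records, paths["seeds"])
        with open(paths["truth"], "w") as fh:
            fh.write("entity\tgenome\tkind\tcomponent\tgene_id\tsubfamily\n")
            for i, m in enumerate(self.truth.modules):
                for comp, gid in m.members.items():
                    fh.write(f"module{i}\t{m.genome_id}\tcomplete\t{comp}\t{gid}\t{m.subfamily}\n")
            for i, dcy in enumerate(self.truth.decoys):
                for comp, gid in dcy.members.items():
                    fh.write(f"decoy{i}\t{dcy.genome_id}\t{dcy.kind}\t{comp}\t{gid}\t-\n")
        return paths


# ---------------------------------------------------------------------------
# canonical topologies


def _topology_from_plan(seq_id: str, plan: list[tuple[str, int]]) -> Topology:
    segments = []
    pos = 1
    for kind, length in plan:
        segments.append((kind, pos, pos + length - 1))
        pos += length
    return Topology(seq_id=seq_id, length=pos - 1, segments=segments)


def hk_topology(seq_id: str, loop_len: int = 8, n_extra_tm: int = 0) -> Topology:
    """Canonical intramembrane-sensing kinase topology: 334 residues, two
    20-residue TMs joined by a short outside loop.  ``n_extra_tm`` inserts
    additional TM segments (architecture decoys)."""
    plan = [("I", 15), ("TM", 20), ("O", loop_len), ("TM", 20)]
    side = "I"
    for _ in range(n_extra_tm):
        plan.append((side, 10))
        plan.append(("TM", 20))
        side = "O" if side == "I" else "I"
    used = sum(length for _k, length in plan)
    plan.append((side, 334 - used))
    return _topology_from_plan(seq_id, plan)


def msd_topology(seq_id: str, o4_len: int = 205, total_len: int = 646) -> Topology:
    """Canonical translocator topology: ten 20-residue TMs, short (10
    residue) connecting loops, and the large extracytoplasmic O4 loop
    between TM7 and TM8.  The C-terminal tail absorbs the remainder."""
    plan: list[tuple[str, int]] = [("I", 10)]
    side = "O"
    for tm in range(1, 10):
        plan.append(("TM", 20))
        loop = o4_len if tm == 7 else 10
        plan.append((side, loop))
        side = "O" if side == "I" else "I"
    plan.append(("TM", 20))
    used = sum(length for _k, length in plan)
    tail = total_len - used
    if tail <= 0:
        raise InputError(f"total_len {total_len} too short for o4_len {o4_len}")
    plan.append((side, tail))
    return _topology_from_plan(seq_id, plan)


def soluble_topology(seq_id: str, length: int) -> Topology:
    return Topology(seq_id=seq_id, length=length, segments=[("I", 1, length)])


# ---------------------------------------------------------------------------
# sequences


def _seq_for_topology(top: Topology, rng: np.random.Generator) -> str:
    out = []
    for kind, start, end in top.segments:
        pool = HYDROPHOBIC_POOL if kind == "TM" else POLAR_POOL
        out.append("".join(rng.choice(list(pool), size=end - start + 1)))
    return "".join(out)


def synthetic_seed_records() -> dict:
    """Deterministic synthetic stand-ins for the four B. subtilis seed
    proteins (BceR 231 aa, BceS 334 aa, BceA 253 aa, BceB 646 aa).

    These are simulated sequences, not database entries: lengths and TM
    architecture match the real seeds, residue content is generated.  Real
    seed FASTAs can be supplied instead wherever seeds are an input.
    """
    rng = np.random.default_rng(_SEED_PROTEIN_RNG_SEED)
    tops = {
        "RR": soluble_topology("BceR_syn", 231),
        "HK": hk_topology("BceS_syn"),
        "NBD": soluble_topology("BceA_syn", 253),
        "MSD": msd_topology("BceB_syn"),
    }
    return {
        comp: SequenceRecord(
            id=top.seq_id,
            residues=_seq_for_topology(top, rng),
            description=f"component={comp} synthetic seed",
        )
        for comp, top in tops.items()
    }


def substitute(residues: str, probs: np.ndarray, rng: np.random.Generator) -> str:
    """Per-site substitution primitive: site i is redrawn uniformly from the
    20-residue alphabet with probability ``probs[i]``.  The single place the
    substitution model lives."""
    residues_arr = np.array(list(residues))
    hit = rng.random(len(residues_arr)) < probs
    n_hit = int(hit.sum())
    if n_hit:
        residues_arr[hit] = rng.choice(list(AMINO_ACIDS), size=n_hit)
    return "".join(residues_arr)


def site_rates_for_topology(top: Topology, region_rates: dict) -> np.ndarray:
    """Per-site substitution rates from a topology: TM residues get
    region_rates['TM'], inside residues 'I', outside residues 'O_short'
    except the large loop after TM7 which gets 'O4'."""
    rates = np.empty(top.length)
    tm_seen = 0
    for kind, start, end in top.segments:
        if kind == "TM":
            tm_seen += 1
            rate = region_rates["TM"]
        elif kind == "I":
            rate = region_rates["I"]
        else:
            rate = region_rates["O4"] if tm_seen == 7 else region_rates["O_short"]
        rates[start - 1 : end] = rate
    return rates


def evolve_family(
    ancestor: SequenceRecord,
    tree: Tree,
    site_rates: np.ndarray,
    rng: np.random.Generator,
) -> tuple[dict, MSA]:
    """Evolve ``ancestor`` down ``tree`` with per-site rates.

    On each branch of length b, site i is redrawn uniformly from the
    alphabet with probability 1 − exp(−site_rates[i]·b).  Returns the leaf
    sequences and the true (gap-free) alignment.
    """
    site_rates = np.asarray(site_rates, dtype=float)
    if site_rates.shape != (len(ancestor.residues),):
        raise InputError("site_rates length must equal ancestor length")
    if (site_rates < 0).any():
        raise InputError("negative substitution rates are not allowed")
    dtree = tree._dtree
    seqs: dict = {}
    dtree.seed_node.sim_seq = ancestor.residues
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            continue
        brlen = node.edge.length or 0.0
        probs = 1.0 - np.exp(-site_rates * brlen)
        node.sim_seq = substitute(node.parent_node.sim_seq, probs, rng)
        if node.is_leaf():
            seqs[node.taxon.label] = SequenceRecord(
                id=node.taxon.label, residues=node.sim_seq
            )
    records = [seqs[label] for label in sorted(seqs)]
    return seqs, MSA(records)


# ---------------------------------------------------------------------------
# random trees and distance matrices (NJ / conservation test support)


def random_tree(n_taxa: int, rng: np.random.Generator, labels: list[str] | None = None) -> Tree:
    """Random unrooted binary topology by sequential taxon attachment, with
    uniform(0.1, 1.0) branch lengths — generically additive, so NJ should
    recover it exactly."""
    if labels is None:
        labels = [f"T{i:02d}" for i in range(n_taxa)]
    if n_taxa < 4:
        raise InputError("need at least 4 taxa")
    import dendropy

    tns = dendropy.TaxonNamespace(labels)

    def blen() -> float:
        return float(rng.uniform(0.1, 1.0))

    # start from a 3-taxon star, then attach each new taxon to a random edge
    root = dendropy.Node()
    leaves = []
    for label in labels[:3]:
        node = dendropy.Node(taxon=tns.get_taxon(label))
        node.edge.length = blen()
        root.add_child(node)
        leaves.append(node)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    for label in labels[3:]:
        edges = [
            node.edge for node in tree.preorder_node_iter() if node.parent_node is not None
        ]
        edge = edges[int(rng.integers(len(edges)))]
        old_child = edge.head_node
        parent = edge.tail_node
        split = dendropy.Node()
        parent.remove_child(old_child)
        parent.add_child(split)
        split.add_child(old_child)
        keep = edge.length
        split.edge.length = keep * 0.5
        old_child.edge.length = keep * 0.5
        new_leaf = dendropy.Node(taxon=tns.get_taxon(label))
        new_leaf.edge.length = blen()
        split.add_child(new_leaf)
    return Tree(tree, rooted=False)


def patristic_matrix(tree: Tree) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length (additive) distance matrix."""
    import dendropy

    pdm = tree._dtree.phylogenetic_distance_matrix()
    labels = sorted(tree.leaf_labels())
    tns = tree._dtree.taxon_namespace
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            t1 = tns.get_taxon(labels[i])
            t2 = tns.get_taxon(labels[j])
            d[i, j] = d[j, i] = pdm.patristic_distance(t1, t2)
    return labels, d


# ---------------------------------------------------------------------------
# genome planting


_BACKGROUND_PRODUCTS = (
    "hypothetical protein",
    "50S ribosomal protein L2",
    "DNA polymerase III subunit beta",
    "enolase",
    "elongation factor Tu",
    "cell division protein FtsZ",
    "phosphoglycerate mutase",
)

_MODULE_PRODUCTS = {
    "RR": "two-component response regulator",
    "HK": "two-component sensor histidine kinase",
    "NBD": "ABC transporter ATP-binding protein",
    "MSD": "ABC transporter permease",
}


def _spread(total: int, bins: int) -> list[int]:
    base, extra = divmod(total, bins)
    return [base + (1 if i < extra else 0) for i in range(bins)]


def plant_genome(cfg: SimConfig) -> SyntheticDataset:
    """Generate the full synthetic genome bundle for ``cfg``.

    Each genome is one contig of ordered genes: runs of background genes
    separate planted complete modules (component order RR, HK, NBD, MSD with
    0..max_intervening_planted background genes inside) and decoys, each of
    which violates exactly its designated rule — an HK with extra TMs, an
    MSD whose TM7–TM8 loop is one residue below/above the accepted window,
    a module missing its MSD, or a module whose genes are scattered beyond
    any clustering gap.  Deterministic under cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)
    seeds = synthetic_seed_records()
    genome_ids = [f"G{i:03d}" for i in range(cfg.n_genomes)]

    modules_per_genome = _spread(cfg.total_modules, cfg.n_genomes)
    decoy_assignments: dict[str, list[str]] = {g: [] for g in genome_ids}
    for kind in DECOY_KINDS:
        count = cfg.decoy_counts.get(kind, 0)
        for i in range(count):
            decoy_assignments[genome_ids[i % cfg.n_genomes]].append(kind)

    features: list[GeneFeature] = []
    proteome: list[SequenceRecord] = []
    topologies: dict = {}
    truth_modules: list[PlantedModule] = []
    truth_decoys: list[PlantedDecoy] = []
    component_of: dict = {}

    div = cfg.divergence

    def derived_sequence(component: str, extra_len: int = 0) -> str:
        base = seeds[component].residues
        if extra_len:
            base = base + "".join(rng.choice(list(POLAR_POOL), size=extra_len))
        probs = np.full(len(base), div)
        return substitute(base, probs, rng)

    for genome_id, n_modules in zip(genome_ids, modules_per_genome):
        gene_counter = 0
        entities: list[tuple[str, str]] = [("module", "")] * n_modules + [
            ("decoy", kind) for kind in decoy_assignments[genome_id]
        ]

        def next_gene_id() -> str:
            nonlocal gene_counter
            gid = f"{genome_id}_g{gene_counter:04d}"
            gene_counter += 1
            return gid

        genome_rows: list[tuple[str, SequenceRecord, Topology, str]] = []

        def add_background(n: int) -> None:
            for _ in range(n):
                gid = next_gene_id()
                length = int(rng.integers(50, 90))
                top = soluble_topology(gid, length)
                seq = SequenceRecord(id=gid, residues=_seq_for_topology(top, rng))
                product = _BACKGROUND_PRODUCTS[int(rng.integers(len(_BACKGROUND_PRODUCTS)))]
                genome_rows.append((gid, seq, top, product))
                component_of[gid] = "none"

        def add_component(component: str, top_maker, extra_len: int = 0) -> str:
            gid = next_gene_id()
            residues = derived_sequence(component, extra_len)
            top = top_maker(gid)
            if top.length != len(residues):
                raise InputError(
                    f"planted {component} length {len(residues)} != topology {top.length}"
                )
            genome_rows.append(
                (gid, SequenceRecord(id=gid, residues=residues), top, _MODULE_PRODUCTS[component])
            )
            component_of[gid] = component
            return gid

        component_tops = {
            "RR": lambda gid: soluble_topology(gid, 231),
            "HK": lambda gid: hk_topology(gid),
            "NBD": lambda gid: soluble_topology(gid, 253),
            "MSD": lambda gid: msd_topology(gid),
        }

        add_background(cfg.background_run)
        for kind, decoy_kind in entities:
            if kind == "module":
                members: dict = {}
                gaps: list[int] = []
                order = ("RR", "HK", "NBD", "MSD")
                for k, component in enumerate(order):
                    members[component] = add_component(component, component_tops[component])
                    if k < len(order) - 1:
                        gap = int(rng.integers(0, cfg.max_intervening_planted + 1))
                        gaps.append(gap)
                        add_background(gap)
                truth_modules.append(
                    PlantedModule(
                        genome_id=genome_id,
                        members=members,
                        intervening_counts=gaps,
                        subfamily="IV",
                    )
                )
            else:
                members = {}
                if decoy_kind == "wrong_tm_count":
                    members["RR"] = add_component("RR", component_tops["RR"])
                    members["HK"] = add_component("HK", lambda gid: hk_topology(gid, n_extra_tm=1))
                    members["NBD"] = add_component("NBD", component_tops["NBD"])
                    members["MSD"] = add_component("MSD", component_tops["MSD"])
                    expected = "tm_count_mismatch"
                elif decoy_kind == "loop_too_short":
                    members["RR"] = add_component("RR", component_tops["RR"])
                    members["HK"] = add_component("HK", component_tops["HK"])
                    members["NBD"] = add_component("NBD", component_tops["NBD"])
                    members["MSD"] = add_component(
                        "MSD", lambda gid: msd_topology(gid, o4_len=99)
                    )
                    expected = "loop_out_of_range"
                elif decoy_kind == "loop_too_long":
                    members["RR"] = add_component("RR", component_tops["RR"])
                    members["HK"] = add_component("HK", component_tops["HK"])
                    members["NBD"] = add_component("NBD", component_tops["NBD"])
                    members["MSD"] = add_component(
                        "MSD",
                        lambda gid: msd_topology(gid, o4_len=401, total_len=800),
                        extra_len=154,
                    )
                    expected = "loop_out_of_range"
                elif decoy_kind == "missing_component":
                    members["RR"] = add_component("RR", component_tops["RR"])
                    members["HK"] = add_component("HK", component_tops["HK"])
                    members["NBD"] = add_component("NBD", component_tops["NBD"])
                    expected = "missing_msd"
                elif decoy_kind == "shuffled_order":
                    for component in ("RR", "HK", "NBD", "MSD"):
                        members[component] = add_component(component, component_tops[component])
                        if component != "MSD":
                            add_background(cfg.background_run)
                    expected = "scattered_beyond_gap"
                else:  # pragma: no cover - guarded by SimConfig validation
                    raise InputError(f"unknown decoy kind {decoy_kind!r}")
                truth_decoys.append(
                    PlantedDecoy(
                        genome_id=genome_id,
                        kind=decoy_kind,
                        members=members,
                        expected_failure=expected,
                    )
                )
            add_background(cfg.background_run)

        for idx, (gid, seq, top, product) in enumerate(genome_rows):
            start = 100 + idx * 3000
            features.append(
                GeneFeature(
                    gene_id=gid,
                    genome_id=genome_id,
                    contig=f"{genome_id}_chr",
                    start=start,
                    end=start + 3 * len(seq.residues) - 1,
                    strand="+" if rng.random() < 0.5 else "-",
                    rank=idx,
                    product=product,
                )
            )
            proteome.append(seq)
            topologies[gid] = top

    truth = TruthTable(
        modules=truth_modules, decoys=truth_decoys, component_of=component_of
    )
    return SyntheticDataset(
        config=cfg,
        features=features,
        proteome=proteome,
        topologies=topologies,
        seeds=seeds,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# reference trees with planted subfamily clades


def plant_reference_trees(
    cfg: SimConfig,
    components: tuple = ("RR", "HK", "NBD", "MSD"),
) -> tuple[dict, dict]:
    """Per-component trees with six monophyletic labelled subfamily clades.

    Each clade holds ``n_refs_per_subfamily`` reference leaves (named
    REF_<component>_<subfamily>_<i>) plus the queries planted into that
    subfamily (named Q<q>_<component>; query q goes to subfamily q mod 6,
    identically across components so concordance is 1 by construction).
    Internal supports are all ``ref_clade_support``.  Returns
    (component -> Tree, query-index -> subfamily truth).
    """
    from .phylo import SUBFAMILIES

    if cfg.n_refs_per_subfamily < 2:
        raise InputError("need at least 2 references per subfamily")
    query_truth = {q: SUBFAMILIES[q % len(SUBFAMILIES)] for q in range(cfg.n_queries)}
    support = f"{cfg.ref_clade_support:g}"
    trees: dict = {}
    for component in components:
        clades = []
        for s_idx, subfamily in enumerate(SUBFAMILIES):
            tips = [
                f"REF_{component}_{subfamily}_{i}"
                for i in range(cfg.n_refs_per_subfamily)
            ] + [f"Q{q}_{component}" for q, fam in query_truth.items() if fam == subfamily]
            # ladder: (t1,(t2,(t3,...)support)support)support
            newick = tips[-1]
            for tip in reversed(tips[:-1]):
                newick = f"({tip},{newick}){support}"
            clades.append(newick)
        text = (
            f"(({clades[0]},{clades[1]}){support},({clades[2]},{clades[3]}){support},"
            f"({clades[4]},{clades[5]}){support});"
        )
        trees[component] = Tree.from_newick(text)
    return trees, query_truth


def reference_map_for(component: str, cfg: SimConfig) -> dict:
    """Leaf→subfamily map matching :func:`plant_reference_trees` labels."""
    from .phylo import SUBFAMILIES

    return {
        f"REF_{component}_{subfamily}_{i}": subfamily
        for subfamily in SUBFAMILIES
        for i in range(cfg.n_refs_per_subfamily)
    }
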