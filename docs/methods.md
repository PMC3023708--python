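# Methods

This note documents the models, rules and numerical choices behind
`bcescan`, and what its synthetic benchmarks do and do not demonstrate.

## Detection model

A Bce-like module is operationalised as a chromosomal cluster of genes
whose products are homologous to the four *B. subtilis* seed proteins
(BceR 231 aa, BceS 334 aa, BceA 253 aa, BceB 646 aa) and whose membrane
components satisfy characteristic topology signatures.

**Component typing.** Each protein is locally aligned (Smith–Waterman,
BLOSUM62, gap open 11 / extend 1) against the four seeds. The score is
normalized by the winning seed's self-alignment score, giving a
deterministic, database-independent similarity in [0, 1]; the default call
threshold is 0.2. E-values are deliberately not used: they need a database
size, which a desk-scale run does not have. Ties between seeds break by the
fixed order RR < HK < NBD < MSD. BLAST tabular import (best bitscore per
query, ≥25 % identity, ≥50 % seed coverage by default) is an alternative
evidence source; all thresholds are configurable and echoed in report
headers.

**Architecture filters.** From a topology (TMHMM segments, or the built-in
hydropathy fallback) the filter tests protein length, exact TM count, and
the length of the inter-TM span after a designated TM:

| rule | length (aa) | TMs | loop tested | window (aa) |
|------|-------------|-----|-------------|-------------|
| hk   | 50–1000     | 2   | after TM1   | 1–20        |
| msd  | 400–1000    | 10  | after TM7   | 100–400     |

Stricter presets (`results_hk12`, `results_hk14`: kinase loop ≤12/≤14;
`results_msd170`: translocator loop >170) reflect the narrower windows used
in published survey counts; they are kept as named variants rather than
silently replacing the defaults, because the two sets of windows are both
defensible readings of the same screen. Every violated condition is
reported, not just the first, which makes decoy diagnostics exact. Loop
sidedness is ignored by default (`require_outside` opts in): predicted side
labels flip with N-terminus orientation, so the filter is stated on the
full inter-TM span.

The loop is measured as the **full inter-TM span** (all residues strictly
between the two TMs), not only its outside-labelled part.

**Hydropathy fallback.** When no topology file is given, a Kyte–Doolittle
sliding window (length 19, cutoff 1.6) marks a residue as TM-candidate if
*any* full window covering it reaches the cutoff; maximal candidate runs of
≥15 residues become TM segments. Covering-window marking (rather than
center-only marking) is used because center-only marking systematically
truncates each hydrophobic core by half a window at both ends and misses
genuine single-span segments. The N-terminal side is fixed to inside by
convention; the default filters do not consume sidedness, so this is
documentation, not biology.

**Clustering.** Per contig, component-called genes in rank order form one
cluster while consecutive component genes are separated by ≤ `max_gap`
(default 3) non-component genes. The tolerance is an explicit assumption —
the source screen never states one — and is configurable and echoed in
reports. Strand is recorded but never splits clusters (modules are defined
by proximity, not co-orientation). Pseudogene-flagged members count toward
composition and are tallied separately. Cluster classes: *complete* (≥1 of
each component), *transporter_only* (only NBD/MSD, no component-called
RR/HK within 5 genes), *foreign_regulator* (only NBD/MSD but a
non-component gene whose product text matches
`response regulator|histidine kinase|sensor` within the scan window — the
salXY pattern), else *partial*. In the scan pipeline, HK calls must pass
the hk rule and MSD calls the msd rule before clustering (failures are
demoted to none); RR and NBD have no architecture gate because no topology
signature defines them — their status refines later through tree placement.

## Subfamily assignment and congruence

Queries are placed on published (imported) trees; the package never infers
ML/Bayesian trees itself. Clade search uses **unrooted bipartition
semantics**: candidate clades are the sides of internal-edge bipartitions
containing the query, at least one reference leaf, and support ≥
`min_support` (default 0.5, the weakest clade support accepted for a
subfamily in the source classification). Pendant (single-leaf) bipartitions
are excluded as candidates: they carry no support annotation and their
complement side would otherwise qualify trivially. The smallest qualifying
clade decides; if its references span more than one subfamily, or no clade
qualifies, the query is unclassified. Supports >1 on read are treated as
bootstrap percentages and divided by 100. The shipped reference map
contains only accessions that are unambiguous from text sources (S. mutans
BceRSAB → II; B. subtilis Bce and S. aureus VraFG/GraRS → IV;
L. monocytogenes AnrAB and S. pyogenes SalXY → V, transporter components
only); it is deliberately sparse and user-extensible, and subfamily VI has
anchors only for NBD/MSD trees — no regulator or kinase belongs to it.

Co-evolution is quantified two ways: cluster-level **concordance** (the
fraction of clusters whose ≥2 classified components agree on one
subfamily) and **Robinson–Foulds distance** between component trees pruned
to shared leaves (≥4 shared leaves required).

**Neighbor joining fallback.** Classical NJ with a deterministic
lexicographic tie-break on label pairs and branch lengths clipped at zero;
the default distance for sequence input is the Poisson-corrected
p-distance −ln(1−p) from pairwise local alignments (gap columns excluded,
p capped at 0.95 to keep the correction finite). This is a fallback for
data exploration, not a substitute for proper phylogenetic inference.

## Conservation profiling

The reference row of the alignment is partitioned by its topology into
regions labelled N→C (I1.., O1.., TM1..; 21 regions for a canonical 10-TM
translocator, O4 being the large loop). Columns where the reference is
gapped belong to no region — region sizes are reference-defined. Identity
of a homolog in a region is (matching columns)/(region columns), a gap in
the homolog counting as a mismatch; empty regions are reported missing,
never 0. The summary gives mean ± sample SD over non-reference rows plus a
whole-protein row, and a Poisson-corrected distance column (−ln mean
identity) is emitted alongside raw identity so both conventions for the
Y-axis of a conservation plot are available. With these definitions the
whole-protein identity is exactly the region-size-weighted mean of region
identities.

## Synthetic data

The generator defines the package's study conditions; its defaults are
fixed, not tuned per run.

* **Genomes.** 20 genomes, 50 complete modules spread evenly, decoy counts
  per kind as configured (the benchmark uses 40 of each of five kinds =
  200). Planted modules use gene order RR, HK, NBD, MSD with 0–2 intervening
  background genes; planted entities are separated by runs of 5 background
  genes so neighbouring entities can never merge under the default
  `max_gap` of 3. Module member sequences are seed copies with per-site
  substitution probability 0.3 — deep enough that recovery is not a string
  match, shallow enough that homology is unambiguous. Each decoy violates
  exactly one rule: a 3-TM kinase (`wrong_tm_count`), a translocator loop
  of 99 or 401 residues — one residue outside the 100–400 window
  (`loop_too_short`/`loop_too_long`), a module without its MSD
  (`missing_component`), or a module scattered at 5-gene spacings
  (`shuffled_order`).
* **Seed stand-ins.** The four seed proteins are synthetic: lengths (231,
  334, 253, 646) and TM architecture match the real *B. subtilis* proteins,
  residues are generated from polar/hydrophobic pools under a fixed
  internal seed. Real seed FASTAs can be substituted anywhere seeds are an
  input.
* **Substitution model.** Along a branch of length b, each site is redrawn
  uniformly from the 20-residue alphabet with probability 1 − exp(−rate·b)
  — a Jukes–Cantor-style randomization under which the expected identity of
  two leaves at distance 2rb is exactly exp(−2rb) + (1 − exp(−2rb))/20, the
  closed form the benchmark checks. The model lives in one function
  (`simulate.substitute`) so an empirical matrix could replace it. Indels
  are off by default, making the true alignment the gap-free site matrix;
  conservative region tests are therefore exact at the column level.
* **Per-region rates.** Defaults rate(TM)=0.2 < rate(I)=rate(O short)=0.5 <
  rate(O4)=1.5 per unit branch length, emulating a strongly conserved
  membrane core and a rapidly diverging large loop.
* **Reference trees.** Six monophyletic subfamily clades per component,
  two reference leaves each, queries planted round-robin and identically
  across components (so planted concordance is 1); internal supports all
  equal a configurable value (1.0, or below threshold to exercise the
  unclassified path).

**What passing these benchmarks shows — and does not.** They demonstrate
the pipeline's logic is exact on noise-free inputs: the filter equals an
independent checker, detection is lossless when topologies are correct, and
tree/conservation queries recover planted truth. They do not show
robustness to the noise of real data — TM-prediction errors, annotation
gaps, fragmented assemblies, compositional bias, indel-rich alignments —
nor can they reproduce historical survey counts, which depend on a specific
past genome collection.

## Problem sizes and determinism

The shipped benchmarks use 1,000 random topologies for the filter check,
the 20-genome/50-module/200-decoy scan, 60 queries per component tree, 100
conservation replicates, 100 NJ matrices and a 10,000-site substitution
check; together they run in well under a minute on one core. All randomness
flows from explicit seeds (`numpy.random.default_rng`); identical
configuration yields byte-identical generator output and reports (modulo
the version line).

## Known limitations

* Component typing assumes one seed per component; paralog-rich families
  with intermediate similarity to two seeds resolve by a fixed tie-break,
  not by evidence weighing.
* The hydropathy fallback is a deliberately simple single-scale predictor;
  it is adequate for synthetic and seed sequences but not a replacement for
  an HMM-based TM predictor on real proteomes.
* Cluster detection is single-contig; modules split across contigs are
  reported as partial clusters.
* The foreign-regulator class depends on product annotation text and will
  miss unannotated regulators.
* Trees are consumed, not inferred; subfamily calls inherit whatever biases
  the imported trees carry.
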