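"""Readers and writers for the external formats the pipeline touches.

All on-disk coordinates are 1-based inclusive (GFF/TMHMM convention);
internal column/offset arithmetic elsewhere in the package is 0-based
half-open, with conversion only at these I/O boundaries.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .errors import InputError

logger = logging.getLogger(__name__)

#: the 20 standard amino acids plus X (unknown)
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
GAP_CHARS = frozenset("-.")


@dataclass
class SequenceRecord:
    """One protein sequence: ``id`` is the first whitespace-delimited word of
    the FASTA header, ``description`` the remainder, ``residues`` the
    uppercase amino-acid string (20 standard letters plus X)."""

    id: str
    residues: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneFeature:
    """A gene on a contig. ``start``/``end`` are 1-based inclusive base-pair
    coordinates; ``rank`` is the 0-based ordinal position of the gene along
    its contig after sorting by start."""

    gene_id: str
    genome_id: str
    contig: str
    start: int
    end: int
    strand: str
    rank: int = -1
    product: str = ""
    pseudo: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(
                f"feature {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise InputError(
                f"feature {self.gene_id}: unknown strand {self.strand!r}"
            )


@dataclass
class MSA:
    """A multiple sequence alignment: records whose residues may contain
    '-'; all rows have identical length."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) > 1:
            offenders = ", ".join(
                f"{r.id}={len(r.residues)}" for r in self.records
            )
            raise InputError(f"unequal alignment lengths: {offenders}")

    @property
    def n_cols(self) -> int:
        return len(self.records[0].residues) if self.records else 0

    def row(self, seq_id: str) -> str:
        for r in self.records:
            if r.id == seq_id:
                return r.residues
        raise InputError(f"sequence {seq_id!r} not in alignment")


def _clean_residues(seq_id: str, raw: str, allow_gaps: bool) -> str:
    out = []
    for ch in raw.upper():
        if ch in AA_ALPHABET:
            out.append(ch)
        elif ch in GAP_CHARS:
            if allow_gaps:
                out.append("-")
            else:
                raise InputError(f"record {seq_id}: gap character in unaligned sequence")
        else:
            logger.warning("record %s: residue %r replaced by X", seq_id, ch)
            out.append("X")
    return "".join(out)


def _records_from_fasta(path: str | Path, allow_gaps: bool) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise InputError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = _clean_residues(rec.id, str(rec.seq), allow_gaps)
        if not residues:
            raise InputError(f"record {rec.id!r} in {path} has an empty sequence")
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    return records


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read unaligned protein FASTA; line wrapping is collapsed, record order
    preserved.  Duplicate ids and empty sequences are hard errors."""
    return _records_from_fasta(path, allow_gaps=False)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_msa(path: str | Path) -> MSA:
    """Read aligned FASTA; '.' gaps are unified to '-'; ragged rows are a
    hard error listing the offenders."""
    return MSA(_records_from_fasta(path, allow_gaps=True))


def write_msa(msa: MSA, path: str | Path) -> None:
    write_fasta(msa.records, path)


_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n", ""}


def _parse_pseudo(token: str) -> bool:
    t = token.strip().lower()
    if t in _TRUTHY:
        return True
    if t in _FALSY:
        return False
    raise InputError(f"unparseable pseudo flag {token!r}")


def _assign_ranks(features: list[GeneFeature]) -> list[GeneFeature]:
    features.sort(key=lambda f: (f.genome_id, f.contig, f.start, f.gene_id))
    counters: dict[tuple[str, str], int] = {}
    for f in features:
        key = (f.genome_id, f.contig)
        f.rank = counters.get(key, 0)
        counters[key] = f.rank + 1
    return features


def _read_features_tsv(path: str | Path) -> list[GeneFeature]:
    features = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"genome", "contig", "gene_id", "start", "end", "strand"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise InputError(
                f"{path}: TSV feature table needs columns {sorted(required)}"
            )
        for i, row in enumerate(reader, start=2):
            try:
                start, end = int(row["start"]), int(row["end"])
            except ValueError as exc:
                raise InputError(f"{path}:{i}: non-integer coordinate") from exc
            features.append(
                GeneFeature(
                    gene_id=row["gene_id"],
                    genome_id=row["genome"],
                    contig=row["contig"],
                    start=start,
                    end=end,
                    strand=row["strand"],
                    product=row.get("product") or "",
                    pseudo=_parse_pseudo(row.get("pseudo") or ""),
                )
            )
    return features


def _gff_attributes(column: str) -> dict[str, str]:
    attrs = {}
    for part in column.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def _read_features_gff3(path: str | Path, genome_id: str | None) -> list[GeneFeature]:
    if genome_id is None:
        genome_id = Path(path).stem
    rows: list[GeneFeature] = []
    kept_types = {"gene", "CDS"}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise InputError(f"{path}:{lineno}: expected 9 GFF3 columns")
            contig, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype not in kept_types:
                continue
            attributes = _gff_attributes(attrs)
            gene_id = attributes.get("ID") or attributes.get("locus_tag")
            if gene_id is None:
                raise InputError(f"{path}:{lineno}: no ID or locus_tag attribute")
            rows.append(
                GeneFeature(
                    gene_id=gene_id,
                    genome_id=genome_id,
                    contig=contig,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    product=attributes.get("product", ""),
                    pseudo=attributes.get("pseudo", "").lower() in _TRUTHY
                    or "pseudo" in attributes
                    and attributes["pseudo"] == "",
                )
            )
    # CDS rows duplicate their parent gene in many dialects; keep one row per id
    dedup: dict[str, GeneFeature] = {}
    for f in rows:
        dedup.setdefault(f.gene_id, f)
    return list(dedup.values())


def read_features(
    path: str | Path, dialect: str = "tsv", genome_id: str | None = None
) -> list[GeneFeature]:
    """Read gene features from a plain TSV table or a minimal GFF3 and return
    them sorted by (contig, start) with per-contig ranks assigned."""
    if dialect == "tsv":
        features = _read_features_tsv(path)
    elif dialect == "gff3":
        features = _read_features_gff3(path, genome_id)
    else:
        raise InputError(f"unknown feature dialect {dialect!r}")
    ids_per_genome: dict[str, set[str]] = {}
    for f in features:
        seen = ids_per_genome.setdefault(f.genome_id, set())
        if f.gene_id in seen:
            raise InputError(f"duplicate gene_id {f.gene_id!r} in genome {f.genome_id}")
        seen.add(f.gene_id)
    return _assign_ranks(features)


def write_features(features: Iterable[GeneFeature], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["genome", "contig", "gene_id", "start", "end", "strand", "product", "pseudo"])
        for f in features:
            writer.writerow(
                [f.genome_id, f.contig, f.gene_id, f.start, f.end, f.strand, f.product, int(f.pseudo)]
            )


_TMHMM_KINDS = {"inside": "I", "outside": "O", "TMhelix": "TM"}


def parse_tmhmm(path: str | Path):
    """Parse TMHMM "long"-format segment lines into per-protein topologies.

    Expected line shape: ``<id>\\tTMHMM2.0\\t<inside|outside|TMhelix>\\t<start>\\t<end>``
    with segments contiguous and 1-based inclusive per id.  Comment lines
    starting with '#' are skipped.  Returns a mapping id -> Topology.
    """
    from .topology import Topology  # deferred: topology builds on io types

    segments: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                cols = line.split()
            if len(cols) != 5:
                raise InputError(f"{path}:{lineno}: expected 5 TMHMM columns")
            seq_id, _program, label, start, end = cols
            if label not in _TMHMM_KINDS:
                raise InputError(f"{path}:{lineno}: unknown segment label {label!r}")
            segments.setdefault(seq_id, []).append(
                (_TMHMM_KINDS[label], int(start), int(end))
            )
    topologies: dict[str, Topology] = {}
    for seq_id, segs in segments.items():
        segs.sort(key=lambda s: s[1])
        expected = 1
        for kind, start, end in segs:
            if start != expected:
                raise InputError(
                    f"{path}: id {seq_id}: segments not contiguous at position {expected}"
                    f" (next segment starts at {start})"
                )
            if end < start:
                raise InputError(f"{path}: id {seq_id}: segment end {end} < start {start}")
            expected = end + 1
        topologies[seq_id] = Topology(seq_id=seq_id, length=expected - 1, segments=segs)
    return topologies


def write_tmhmm(topologies, path: str | Path) -> None:
    """Write topologies in the TMHMM long segment-line format."""
    inverse = {v: k for k, v in _TMHMM_KINDS.items()}
    with open(path, "w") as fh:
        for seq_id in topologies:
            top = topologies[seq_id]
            for kind, start, end in top.segments:
                fh.write(f"{seq_id}\tTMHMM2.0\t{inverse[kind]}\t{start}\t{end}\n")


def parse_newick(text: str):
    """Parse a single newick statement into a support-normalized Tree.

    Numeric internal-node labels are read as supports; values above 1 are
    treated as bootstrap percentages and divided by 100.  Unbalanced
    parentheses are a hard error reporting the character offset.
    """
    from .phylo import Tree

    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise InputError(f"unbalanced ')' at character {offset}")
    if depth != 0:
        raise InputError(
            f"unbalanced '(' — {depth} unclosed at end of statement (length {len(text)})"
        )
    return Tree.from_newick(text)


def read_newick(path: str | Path):
    return parse_newick(Path(path).read_text().strip())
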