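"""Component typing by similarity to the four B. subtilis Bce seeds.

Each proteome entry is assigned one of RR (response regulator, BceR-like),
HK (histidine kinase, BceS-like), NBD (ATPase, BceA-like), MSD
(translocator, BceB-like) or none.  Similarity comes either from built-in
Smith–Waterman local alignment against seed sequences (BLOSUM62, affine
gaps) or from imported BLAST tabular rows.  The decision threshold is a
seed-self-score-normalized fraction rather than an E-value: it is
deterministic and independent of any database size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import InputError
from .io import SequenceRecord, read_fasta

logger = logging.getLogger(__name__)

#: fixed component precedence used for tie-breaking
COMPONENT_ORDER = ("RR", "HK", "NBD", "MSD")


@dataclass
class AlignmentResult:
    query_id: str
    subject_id: str
    score: float
    aligned_pairs: int
    identical_pairs: int

    @property
    def identity(self) -> float:
        return self.identical_pairs / self.aligned_pairs if self.aligned_pairs else 0.0


@dataclass
class ComponentCall:
    """Best-seed component assignment for one protein.

    ``normalized_score`` is the raw local-alignment score divided by the
    winning seed's self-score, so a seed aligned to itself scores exactly 1.
    """

    seq_id: str
    component: str  # RR | HK | NBD | MSD | none
    best_seed: str
    score: float
    normalized_score: float


def _make_aligner(gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def sw_align(
    a: SequenceRecord,
    b: SequenceRecord,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> AlignmentResult:
    """Optimal Smith–Waterman local alignment under BLOSUM62 with affine
    gaps (first gap residue costs ``gap_open``, each further one
    ``gap_extend``).  Score is in substitution-matrix units and never
    negative; sequences with no positively scoring pair align empty with
    score 0."""
    if not a.residues or not b.residues:
        raise InputError("cannot align an empty sequence")
    aligner = _make_aligner(gap_open, gap_extend)
    score = aligner.score(a.residues, b.residues)
    if score <= 0:
        return AlignmentResult(a.id, b.id, 0.0, 0, 0)
    alignment = aligner.align(a.residues, b.residues)[0]
    aligned = identical = 0
    for (qs, qe), (ss, se) in zip(*alignment.aligned):
        aligned += qe - qs
        identical += sum(
            1 for qa, sb in zip(a.residues[qs:qe], b.residues[ss:se]) if qa == sb
        )
    return AlignmentResult(a.id, b.id, float(score), aligned, identical)


def read_seeds(path: str | Path) -> dict[str, SequenceRecord]:
    """Read a seeds FASTA whose headers carry ``component=RR|HK|NBD|MSD``.

    Returns a mapping component -> seed record; exactly one seed per
    component is required.
    """
    seeds: dict[str, SequenceRecord] = {}
    for rec in read_fasta(path):
        tag = None
        for token in rec.description.split():
            if token.startswith("component="):
                tag = token.split("=", 1)[1]
        if tag is None:
            continue
        if tag not in COMPONENT_ORDER:
            raise InputError(f"seed {rec.id}: unknown component tag {tag!r}")
        if tag in seeds:
            raise InputError(f"duplicate seed for component {tag}")
        seeds[tag] = rec
    missing = [c for c in COMPONENT_ORDER if c not in seeds]
    if missing:
        raise InputError(f"missing seed component(s): {', '.join(missing)}")
    return seeds


def call_components(
    proteome: list[SequenceRecord],
    seeds: dict[str, SequenceRecord],
    min_norm_score: float = 0.2,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> list[ComponentCall]:
    """Assign each protein the component of its best seed.

    The best seed is the one maximizing score normalized by that seed's
    self-score; below ``min_norm_score`` for all seeds the call is none.
    Ties break by the fixed order RR < HK < NBD < MSD.
    """
    missing = [c for c in COMPONENT_ORDER if c not in seeds]
    if missing:
        raise InputError(f"missing seed component(s): {', '.join(missing)}")
    aligner = _make_aligner(gap_open, gap_extend)
    self_scores = {
        comp: max(float(aligner.score(seeds[comp].residues, seeds[comp].residues)), 0.0)
        for comp in COMPONENT_ORDER
    }
    calls: list[ComponentCall] = []
    for rec in proteome:
        best_comp, best_norm, best_score = "none", 0.0, 0.0
        for comp in COMPONENT_ORDER:
            # score-only pass: the call needs no traceback
            score = max(float(aligner.score(rec.residues, seeds[comp].residues)), 0.0)
            norm = score / self_scores[comp]
            if norm > best_norm:
                best_comp, best_norm, best_score = comp, norm, score
        if best_norm < min_norm_score:
            calls.append(ComponentCall(rec.id, "none", best_comp, best_score, best_norm))
        else:
            calls.append(
                ComponentCall(rec.id, best_comp, seeds[best_comp].id, best_score, best_norm)
            )
    return calls


def import_blast_tab(
    path: str | Path,
    seed_components: dict[str, str],
    seed_lengths: dict[str, int],
    min_identity: float = 25.0,
    min_coverage: float = 0.5,
) -> list[ComponentCall]:
    """Turn 12-column BLAST tabular rows (``-outfmt 6``) into component calls.

    ``seed_components`` maps subject id -> component tag; ``seed_lengths``
    maps subject id -> full seed length (for subject coverage).  Rows are
    filtered by percent identity and seed coverage; the best bitscore per
    query wins, ties breaking by the fixed component order.
    """
    best: dict[str, tuple[float, int, str, str]] = {}
    order = {c: i for i, c in enumerate(COMPONENT_ORDER)}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise InputError(f"{path}:{lineno}: expected 12 BLAST columns, got {len(cols)}")
            try:
                query, subject = cols[0], cols[1]
                pident = float(cols[2])
                sstart, send = int(cols[8]), int(cols[9])
                bitscore = float(cols[11])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: malformed BLAST row") from exc
            if subject not in seed_components:
                raise InputError(f"{path}:{lineno}: subject {subject!r} is not a tagged seed")
            if pident < min_identity:
                continue
            coverage = (abs(send - sstart) + 1) / seed_lengths[subject]
            if coverage < min_coverage:
                continue
            comp = seed_components[subject]
            key = (-bitscore, order[comp])
            if query not in best or key < (-best[query][0], best[query][1]):
                best[query] = (bitscore, order[comp], comp, subject)
    return [
        ComponentCall(
            seq_id=q,
            component=comp,
            best_seed=subject,
            score=bitscore,
            normalized_score=float("nan"),
        )
        for q, (bitscore, _o, comp, subject) in sorted(best.items())
    ]
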