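"""Membrane-topology algebra.

A :class:`Topology` is an ordered segmentation of a protein into inside (I),
outside (O) and transmembrane (TM) stretches — the representation produced
by TMHMM-style predictors.  This module counts TM segments, extracts the
inter-TM loops (with sidedness) that the architecture filters test, and
provides a Kyte–Doolittle sliding-window predictor as a fallback when no
topology annotation is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .io import SequenceRecord

SegmentKind = str  # "I" | "O" | "TM"


@dataclass
class Topology:
    """Ordered segmentation of one protein into I/O/TM stretches.

    Segments are (kind, start, end), 1-based inclusive, and must tile
    [1, length] exactly.  Two TM segments are never adjacent, and the non-TM
    segments alternate sides across each TM (membrane crossing flips the
    compartment).
    """

    seq_id: str
    length: int
    segments: list[tuple[SegmentKind, int, int]]

    def __post_init__(self) -> None:
        if not self.segments:
            raise InputError(f"{self.seq_id}: topology has no segments")
        expected = 1
        prev_kind = None
        prev_side = None
        for kind, start, end in self.segments:
            if kind not in ("I", "O", "TM"):
                raise InputError(f"{self.seq_id}: unknown segment kind {kind!r}")
            if start != expected or end < start:
                raise InputError(
                    f"{self.seq_id}: segments do not tile [1,{self.length}] "
                    f"(segment {kind} {start}-{end}, expected start {expected})"
                )
            if kind == "TM" and prev_kind == "TM":
                raise InputError(f"{self.seq_id}: two adjacent TM segments")
            if kind in ("I", "O"):
                if kind == prev_kind:
                    raise InputError(f"{self.seq_id}: repeated {kind} segment without TM")
                if prev_side is not None and kind == prev_side and prev_kind == "TM":
                    raise InputError(
                        f"{self.seq_id}: side does not alternate across TM at {start}"
                    )
                prev_side = kind
            prev_kind = kind
            expected = end + 1
        if expected - 1 != self.length:
            raise InputError(
                f"{self.seq_id}: segments cover [1,{expected - 1}] but length is {self.length}"
            )


@dataclass(frozen=True)
class LoopSpan:
    """The stretch of residues strictly between TM ``after_tm`` and TM
    ``after_tm``+1, with the side (I/O) of the intervening non-TM segment."""

    after_tm: int
    side: SegmentKind
    length: int

    @property
    def before_tm(self) -> int:
        return self.after_tm + 1


def tm_count(top: Topology) -> int:
    """Number of transmembrane segments."""
    return sum(1 for kind, _s, _e in top.segments if kind == "TM")


def inter_tm_loops(top: Topology) -> list[LoopSpan]:
    """The tm_count−1 loops between consecutive TM segments, N→C.

    Loop k covers every residue strictly between TM k and TM k+1; its side is
    that of the intervening non-TM segment.  Proteins with fewer than two TMs
    have no loops (empty list).
    """
    loops: list[LoopSpan] = []
    tm_index = 0
    pending_side: SegmentKind | None = None
    pending_len = 0
    after_tm = 0
    for kind, start, end in top.segments:
        if kind == "TM":
            tm_index += 1
            if after_tm and pending_side is not None:
                loops.append(LoopSpan(after_tm=after_tm, side=pending_side, length=pending_len))
            after_tm = tm_index
            pending_side, pending_len = None, 0
        else:
            pending_side = kind
            pending_len = end - start + 1
    return loops


def tails(top: Topology) -> tuple[int, int]:
    """(N-terminal, C-terminal) non-TM tail lengths; 0 when the protein
    starts or ends in a TM segment."""
    first = top.segments[0]
    last = top.segments[-1]
    n_tail = (first[2] - first[1] + 1) if first[0] != "TM" else 0
    c_tail = (last[2] - last[1] + 1) if last[0] != "TM" else 0
    if tm_count(top) == 0:
        return top.length, 0
    return n_tail, c_tail


#: Kyte–Doolittle hydropathy scale; X is treated as neutral (0).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}


def predict_topology_kd(
    seq: SequenceRecord,
    window: int = 19,
    cutoff: float = 1.6,
    min_tm_len: int = 15,
) -> Topology:
    """Sliding-window Kyte–Doolittle topology prediction.

    A residue is a TM candidate when it lies inside at least one full window
    whose mean hydropathy reaches ``cutoff``; maximal candidate runs of at
    least ``min_tm_len`` residues become TM segments.  Sides are assigned by
    convention: the N-terminus starts inside and the side flips across each
    TM.  This is a fallback for synthetic or seed sequences, not a
    re-implementation of an HMM predictor.
    """
    if window % 2 != 1:
        raise InputError("window must be odd")
    n = len(seq.residues)
    if n < window:
        raise InputError(
            f"{seq.id}: sequence length {n} shorter than window {window}"
        )
    half = window // 2
    scores = np.array([KYTE_DOOLITTLE[ch] for ch in seq.residues])
    means = np.convolve(scores, np.ones(window) / window, mode="valid")  # centers half..n-1-half
    candidate = np.zeros(n, dtype=bool)
    for center_off in np.nonzero(means >= cutoff)[0]:
        center = center_off + half
        candidate[center - half : center + half + 1] = True

    # maximal candidate runs >= min_tm_len become TM segments (0-based half-open)
    tm_runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if candidate[i]:
            j = i
            while j < n and candidate[j]:
                j += 1
            if j - i >= min_tm_len:
                tm_runs.append((i, j))
            i = j
        else:
            i += 1

    segments: list[tuple[SegmentKind, int, int]] = []
    side: SegmentKind = "I"
    pos = 0
    for run_start, run_end in tm_runs:
        if run_start > pos:
            segments.append((side, pos + 1, run_start))
        segments.append(("TM", run_start + 1, run_end))
        side = "O" if side == "I" else "I"
        pos = run_end
    if pos < n:
        segments.append((side, pos + 1, n))
    return Topology(seq_id=seq.id, length=n, segments=segments)
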