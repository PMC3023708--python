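"""Per-region conservation profiling of a reference-anchored alignment.

The reference protein's topology partitions its residues into labelled
regions — intracellular segments I1..I6, extracellular loops O1..O5 (O4
being the large loop of BceB-like translocators) and transmembrane
segments TM1..TM10.  Alignment columns inherit the region of the reference
residue they carry; columns where the reference is gapped belong to no
region.  Per region, each homolog's identity to the reference is the
fraction of region columns carrying the identical residue, with a gap in
the homolog counting as a mismatch.  A Poisson-corrected distance view
(−ln identity) is emitted alongside raw identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .io import MSA
from .topology import Topology


@dataclass
class RegionPartition:
    """Ordered mapping of region label -> 0-based MSA column indices whose
    reference residue falls in that region."""

    ref_id: str
    regions: dict[str, list[int]]  # insertion-ordered, N to C

    @property
    def labels(self) -> list[str]:
        return list(self.regions)

    @property
    def all_columns(self) -> list[int]:
        return [c for cols in self.regions.values() for c in cols]


def region_labels(top: Topology) -> list[str]:
    """N→C region labels for a topology: I/O segments numbered separately
    (I1.., O1..) and TM segments TM1.. — 21 labels for a canonical 10-TM
    translocator (I1..I6, O1..O5, TM1..TM10 interleaved)."""
    counts = {"I": 0, "O": 0, "TM": 0}
    labels = []
    for kind, _s, _e in top.segments:
        counts[kind] += 1
        labels.append(f"{kind}{counts[kind]}")
    return labels


def partition_regions(msa: MSA, ref_id: str, ref_top: Topology) -> RegionPartition:
    """Assign MSA columns to the reference topology's regions.

    The ungapped reference row must be exactly ``ref_top.length`` residues;
    a mismatch is a hard error stating both lengths.
    """
    ref_row = msa.row(ref_id)
    ungapped = sum(1 for ch in ref_row if ch != "-")
    if ungapped != ref_top.length:
        raise InputError(
            f"reference {ref_id}: alignment has {ungapped} residues but the "
            f"topology covers {ref_top.length}"
        )
    labels = region_labels(ref_top)
    # residue index (0-based) -> region label
    residue_region: list[str] = []
    for label, (kind, start, end) in zip(labels, ref_top.segments):
        residue_region.extend([label] * (end - start + 1))
    regions: dict[str, list[int]] = {label: [] for label in labels}
    residue = 0
    for col, ch in enumerate(ref_row):
        if ch == "-":
            continue
        regions[residue_region[residue]].append(col)
        residue += 1
    return RegionPartition(ref_id=ref_id, regions=regions)


def region_identity(
    msa: MSA, ref_id: str, other_id: str, part: RegionPartition
) -> dict[str, float | None]:
    """Fractional identity of ``other_id`` to the reference in each region.

    A gap in the other sequence counts as a mismatch; an empty region is
    reported as None (undefined), never as 0.
    """
    ref_row = msa.row(ref_id)
    other_row = msa.row(other_id)
    out: dict[str, float | None] = {}
    for label, cols in part.regions.items():
        if not cols:
            out[label] = None
            continue
        matches = sum(1 for c in cols if other_row[c] == ref_row[c])
        out[label] = matches / len(cols)
    return out


@dataclass
class ConservationProfile:
    ref_id: str
    n_others: int
    per_pair: pd.DataFrame  # columns: other_id, region, identity
    summary: pd.DataFrame  # columns: region, n_cols, mean, sd, n, poisson_distance

    def ranking(self) -> list[str]:
        """Region labels ordered by increasing mean identity (least
        conserved first); the whole-protein row is excluded."""
        rows = self.summary[self.summary.region != "whole"].dropna(subset=["mean"])
        return list(rows.sort_values(["mean", "region"]).region)


def conservation_profile(msa: MSA, ref_id: str, part: RegionPartition) -> ConservationProfile:
    """Mean ± sample SD identity per region over all non-reference rows,
    plus a whole-protein row restricted to reference-anchored columns."""
    others = [r.id for r in msa.records if r.id != ref_id]
    if not others:
        raise InputError("conservation profile needs at least 2 sequences")
    pair_rows = []
    for other in others:
        idents = region_identity(msa, ref_id, other, part)
        for label, value in idents.items():
            pair_rows.append({"other_id": other, "region": label, "identity": value})
        # whole-protein identity over all reference-anchored columns
        cols = part.all_columns
        ref_row, other_row = msa.row(ref_id), msa.row(other)
        whole = (
            sum(1 for c in cols if other_row[c] == ref_row[c]) / len(cols)
            if cols
            else None
        )
        pair_rows.append({"other_id": other, "region": "whole", "identity": whole})
    per_pair = pd.DataFrame(pair_rows)

    summary_rows = []
    for label in list(part.regions) + ["whole"]:
        values = per_pair.loc[
            (per_pair.region == label) & per_pair.identity.notna(), "identity"
        ].to_numpy(dtype=float)
        n_cols = len(part.regions.get(label, part.all_columns))
        if values.size == 0:
            summary_rows.append(
                {"region": label, "n_cols": n_cols, "mean": None, "sd": None,
                 "n": 0, "poisson_distance": None}
            )
            continue
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
        poisson = -math.log(mean) if mean > 0 else float("inf")
        summary_rows.append(
            {"region": label, "n_cols": n_cols, "mean": mean, "sd": sd,
             "n": int(values.size), "poisson_distance": poisson}
        )
    summary = pd.DataFrame(summary_rows)
    return ConservationProfile(
        ref_id=ref_id, n_others=len(others), per_pair=per_pair, summary=summary
    )
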