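"""Architecture filters for Bce-like module components.

The intramembrane-sensing histidine kinase (BceS-like) signature is a
protein of 50–1000 residues with exactly two TM segments joined by a short
(1–20 residue) loop; the BceB-like translocator signature is 400–1000
residues, exactly ten TM segments, and a long (100–400 residue)
extracytoplasmic loop between TM7 and TM8.  Stricter variants observed in
published survey counts (loop ≤12, ≤14, >170) are exposed as named presets
rather than silently replacing the defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import InputError
from .topology import Topology, inter_tm_loops, tm_count

logger = logging.getLogger(__name__)

FAILURE_KINDS = (
    "length_out_of_range",
    "tm_count_mismatch",
    "loop_out_of_range",
    "loop_side_mismatch",
    "too_few_tms",
)


@dataclass(frozen=True)
class ArchitectureRule:
    """One pass/fail architecture signature.

    ``loop_after_tm`` selects the inter-TM span tested (1-based TM index of
    the preceding TM); ``require_outside`` additionally demands that span be
    extracytoplasmic.
    """

    name: str
    min_len: int
    max_len: int
    tm_required: int
    loop_after_tm: int
    loop_min: int
    loop_max: int
    require_outside: bool = False

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise InputError(f"rule {self.name}: min_len > max_len")
        if self.loop_min > self.loop_max:
            raise InputError(f"rule {self.name}: loop_min > loop_max")
        if not (1 <= self.loop_after_tm < self.tm_required):
            raise InputError(
                f"rule {self.name}: loop_after_tm must lie in [1, tm_required-1]"
            )


@dataclass
class ArchitectureCall:
    """Verdict of one rule on one topology; every violated condition is
    listed, not just the first."""

    seq_id: str
    rule_name: str
    passed: bool
    failures: list[str] = field(default_factory=list)
    tm_count: int = 0
    loop_len: int | None = None
    loop_side: str | None = None
    length: int = 0


def default_rules() -> dict[str, ArchitectureRule]:
    """The two default signatures (hk, msd) plus the stricter survey presets
    results_hk12 / results_hk14 (kinase loop ≤12 / ≤14) and results_msd170
    (translocator loop >170)."""
    return {
        "hk": ArchitectureRule("hk", 50, 1000, 2, 1, 1, 20),
        "msd": ArchitectureRule("msd", 400, 1000, 10, 7, 100, 400),
        "results_hk12": ArchitectureRule("results_hk12", 50, 1000, 2, 1, 1, 12),
        "results_hk14": ArchitectureRule("results_hk14", 50, 1000, 2, 1, 1, 14),
        "results_msd170": ArchitectureRule("results_msd170", 400, 1000, 10, 7, 171, 400),
    }


def classify_architecture(top: Topology, rule: ArchitectureRule) -> ArchitectureCall:
    """Test one topology against one rule.

    Pass requires: protein length within [min_len, max_len]; TM count exactly
    tm_required; the inter-TM span after TM ``loop_after_tm`` within
    [loop_min, loop_max]; and, when required, that span on the outside.
    A pure function: identical inputs always yield the identical verdict.
    """
    failures: list[str] = []
    n_tm = tm_count(top)
    if not (rule.min_len <= top.length <= rule.max_len):
        failures.append("length_out_of_range")
    if n_tm != rule.tm_required:
        failures.append("tm_count_mismatch")
    loop_len: int | None = None
    loop_side: str | None = None
    if n_tm < rule.loop_after_tm + 1:
        failures.append("too_few_tms")
    else:
        span = inter_tm_loops(top)[rule.loop_after_tm - 1]
        loop_len, loop_side = span.length, span.side
        if not (rule.loop_min <= span.length <= rule.loop_max):
            failures.append("loop_out_of_range")
        if rule.require_outside and span.side != "O":
            failures.append("loop_side_mismatch")
    return ArchitectureCall(
        seq_id=top.seq_id,
        rule_name=rule.name,
        passed=not failures,
        failures=failures,
        tm_count=n_tm,
        loop_len=loop_len,
        loop_side=loop_side,
        length=top.length,
    )


def screen_proteome(
    topologies: dict[str, Topology],
    rules: dict[str, ArchitectureRule] | list[ArchitectureRule],
    required_ids: dict[str, set[str]] | None = None,
) -> list[ArchitectureCall]:
    """Apply every rule to every topology; one call per (id, rule).

    ``required_ids`` maps a rule name to ids that must be screened by that
    rule; an id with no topology yields a failed call (tm_count_mismatch)
    and a logged warning rather than silently disappearing.
    """
    if isinstance(rules, dict):
        rules = list(rules.values())
    calls = [
        classify_architecture(top, rule)
        for seq_id, top in topologies.items()
        for rule in rules
    ]
    if required_ids:
        by_name = {r.name: r for r in rules}
        for rule_name, ids in required_ids.items():
            if rule_name not in by_name:
                continue
            for seq_id in sorted(ids - set(topologies)):
                logger.warning(
                    "no topology for %s; recording a failed %s call", seq_id, rule_name
                )
                calls.append(
                    ArchitectureCall(
                        seq_id=seq_id,
                        rule_name=rule_name,
                        passed=False,
                        failures=["tm_count_mismatch"],
                    )
                )
    counts: dict[str, int] = {}
    for c in calls:
        if c.passed:
            counts[c.rule_name] = counts.get(c.rule_name, 0) + 1
    for rule in rules:
        logger.info("rule %s: %d passing", rule.name, counts.get(rule.name, 0))
    return calls


def calls_to_frame(calls: list[ArchitectureCall]) -> pd.DataFrame:
    """Tabular view of architecture calls (one row per id × rule)."""
    return pd.DataFrame(
        {
            "seq_id": [c.seq_id for c in calls],
            "rule": [c.rule_name for c in calls],
            "passed": [c.passed for c in calls],
            "length": [c.length for c in calls],
            "tm_count": [c.tm_count for c in calls],
            "loop_len": [c.loop_len for c in calls],
            "failures": [";".join(c.failures) for c in calls],
        }
    )
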