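"""Sequence-level descriptor aggregation and the AEx score.

Each of the eight descriptors is aggregated from per-residue values by
one of two rules:

* SUM  — AM, AC, ROT, HBA, IP, NON: the value of the sequence is the sum
  of per-residue values weighted by occurrence counts.
* MEAN — QPCaco, QPlogS: the same weighted sum divided by N, where N
  defaults to the number of *distinct* residue types in the sequence
  (the DISTINCT mode); dividing by sequence length (LENGTH mode) is kept
  selectable because the two coincide only for repeat-free sequences.

The score combining six of these is

    AEx = ln(AM - IP + AC * ROT) - (QPCaco - NON)

AEx is undefined whenever the log argument is non-positive; that case is
reported as NaN (with a warning) rather than an exception so that window
scanners can skip such windows gracefully.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

DESCRIPTORS = ("AM", "AC", "ROT", "HBA", "QPCaco", "IP", "NON", "QPlogS")

SUM = "SUM"
MEAN = "MEAN"

#: Aggregation rule per descriptor.
RULES: dict[str, str] = {
    "AM": SUM, "AC": SUM, "ROT": SUM, "HBA": SUM, "IP": SUM, "NON": SUM,
    "QPCaco": MEAN, "QPlogS": MEAN,
}

#: Descriptors whose per-residue values are integer counts.
INTEGER_DESCRIPTORS = ("AM", "AC", "ROT", "NON")

DISTINCT = "distinct"
LENGTH = "length"


@dataclass(frozen=True)
class ResidueParamTable:
    """Per-residue values of one descriptor plus its aggregation rule."""

    descriptor: str
    rule: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if self.rule not in (SUM, MEAN):
            raise ValueError(f"unknown rule {self.rule!r}")
        expected = RULES.get(self.descriptor)
        if expected is not None and expected != self.rule:
            raise ValueError(
                f"descriptor {self.descriptor} uses the {expected} rule, not {self.rule}"
            )


@dataclass(frozen=True)
class SequenceDescriptors:
    """The eight aggregated descriptor values and AEx for one sequence.

    ``aex`` is NaN when the score is undefined (non-positive log argument).
    """

    sequence: str
    sp: dict[str, float] = field(default_factory=dict)
    aex: float = math.nan

    @property
    def aex_defined(self) -> bool:
        return not math.isnan(self.aex)


def _residue_counts(sequence: str, table: ResidueParamTable) -> dict[str, int]:
    counts: dict[str, int] = {}
    for pos, ch in enumerate(sequence, start=1):
        if ch not in table.values:
            raise KeyError(
                f"residue {ch!r} at position {pos} has no value in the "
                f"{table.descriptor} table"
            )
        counts[ch] = counts.get(ch, 0) + 1
    return counts


def sum_parameter(sequence: str, table: ResidueParamTable) -> float:
    """Sum-rule aggregation: sum of per-residue values times occurrence counts."""
    if table.rule != SUM:
        raise ValueError(f"{table.descriptor} is not a SUM descriptor")
    counts = _residue_counts(sequence, table)
    return sum(table.values[ch] * n for ch, n in counts.items())


def mean_parameter(
    sequence: str, table: ResidueParamTable, denominator_mode: str = DISTINCT
) -> float:
    """Mean-rule aggregation: weighted sum divided by N.

    N is the count of distinct residue types (DISTINCT, default) or the
    sequence length (LENGTH).
    """
    if table.rule != MEAN:
        raise ValueError(f"{table.descriptor} is not a MEAN descriptor")
    if not sequence:
        raise ValueError("mean aggregation undefined for an empty sequence")
    counts = _residue_counts(sequence, table)
    total = sum(table.values[ch] * n for ch, n in counts.items())
    n = sequence_denominator(sequence, denominator_mode)
    return total / n


def sequence_denominator(sequence: str, denominator_mode: str = DISTINCT) -> int:
    if denominator_mode == DISTINCT:
        return len(set(sequence))
    if denominator_mode == LENGTH:
        return len(sequence)
    raise ValueError(f"unknown denominator mode {denominator_mode!r}")


def compute_aex(
    am: float, ac: float, rot: float, ip: float, qpcaco: float, non: float
) -> float:
    """AEx = ln(AM - IP + AC*ROT) - (QPCaco - NON); NaN if the log argument <= 0."""
    args = (am, ac, rot, ip, qpcaco, non)
    if not all(math.isfinite(v) for v in args):
        raise ValueError(f"non-finite AEx input: {args}")
    arg = am - ip + ac * rot
    if arg <= 0:
        log.warning("AEx undefined: AM - IP + AC*ROT = %g <= 0", arg)
        return math.nan
    return math.log(arg) - (qpcaco - non)


def compute_descriptors(
    sequence: str,
    tables: dict[str, ResidueParamTable],
    denominator_mode: str = DISTINCT,
) -> SequenceDescriptors:
    """Aggregate all eight descriptors for a sequence and compute AEx."""
    missing = [d for d in DESCRIPTORS if d not in tables]
    if missing:
        raise ValueError(f"missing parameter tables for {missing}")
    sp: dict[str, float] = {}
    for desc in DESCRIPTORS:
        table = tables[desc]
        if table.rule == SUM:
            sp[desc] = sum_parameter(sequence, table)
        else:
            sp[desc] = mean_parameter(sequence, table, denominator_mode)
    aex = compute_aex(
        sp["AM"], sp["AC"], sp["ROT"], sp["IP"], sp["QPCaco"], sp["NON"]
    )
    return SequenceDescriptors(sequence=sequence, sp=sp, aex=aex)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching how the reference values are printed."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor
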