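"""Quadrant classification in the (QPlogS, AEx) plane, Cooper validation
statistics, and the sliding-window protein scanner.

The four classes partition the plane by the signs of aqueous solubility
(QPlogS) and the AEx score; class D (both non-positive) flags
aggregation-prone candidates. The class predicates overlap on the zero
boundaries, so they are evaluated in the fixed order A, B, C, D with the
first match winning:

    A: QPlogS >  0 and AEx <  0
    B: QPlogS >= 0 and AEx >  0
    C: QPlogS <  0 and AEx >= 0
    D: QPlogS <= 0 and AEx <= 0

One cell, QPlogS > 0 with AEx = 0, is covered by none of the four rules
and is reported as U (unclassifiable) rather than silently forced into a
class.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

from .descriptors import (
    DESCRIPTORS,
    DISTINCT,
    ResidueParamTable,
    SequenceDescriptors,
    compute_descriptors,
)
from .reference_data import CANONICAL_RESIDUES, SequenceRecord

log = logging.getLogger(__name__)

CLASSES = ("A", "B", "C", "D")
UNCLASSIFIABLE = "U"

#: Class D is the aggregation-prone ("positive") call.
POSITIVE_CLASS = "D"


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with APR-in-class-D as the positive call."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class CooperStats:
    """The nine Cooper validation statistics, each as a percentage.

    ``pas`` follows its published defining equation Tn/(Tn + Fp), which
    makes it numerically identical to specificity; see the methods note
    for the conflict with the separately published value.
    """

    sn: float
    sp: float
    ac: float
    er: float
    pp: float
    np: float
    fp_oc: float
    fn_uc: float
    pas: float


@dataclass(frozen=True)
class WindowCall:
    """One scored window of a scanned protein (1-based inclusive coordinates)."""

    parent_id: str
    start: int
    end: int
    window_sequence: str
    descriptors: SequenceDescriptors | None
    assigned_class: str

    @property
    def is_apr_candidate(self) -> bool:
        return self.assigned_class == POSITIVE_CLASS


def assign_class(qplogs: float, aex: float) -> str:
    """Assign the quadrant class for one (QPlogS, AEx) point.

    Raises
    ------
    ValueError
        If ``aex`` is NaN (undefined score) — callers scanning windows
        should skip such windows instead.
    """
    if math.isnan(aex):
        raise ValueError("AEx undefined for this sequence; skip the window")
    if qplogs > 0 and aex < 0:
        return "A"
    if qplogs >= 0 and aex > 0:
        return "B"
    if qplogs < 0 and aex >= 0:
        return "C"
    if qplogs <= 0 and aex <= 0:
        return "D"
    return UNCLASSIFIABLE  # only QPlogS > 0 with AEx == 0 lands here


def classify_dataset(
    records: list[SequenceRecord],
    use_printed: bool = True,
    tables: dict[str, ResidueParamTable] | None = None,
    denominator_mode: str = DISTINCT,
) -> tuple[dict[str, Counter], ConfusionCounts]:
    """Classify every record and build the APR-vs-control confusion table.

    In reproduction mode (``use_printed``, the default) classes come
    straight from the published QPlogS and AEx columns. In scoring mode
    descriptors are recomputed from ``tables``; the two modes are never
    mixed in one call. Tregitopes receive class labels in the per-group
    tally but are excluded from the confusion counts, which cover only
    the APR and CONTROL groups.
    """
    if not records:
        raise ValueError("no records to classify")
    if not use_printed and tables is None:
        raise ValueError("scoring mode requires per-residue parameter tables")
    per_group: dict[str, Counter] = {}
    tp = tn = fp = fn = 0
    for rec in records:
        if use_printed:
            qplogs, aex = rec.qplogs, rec.aex_printed
        else:
            sd = compute_descriptors(rec.sequence, tables, denominator_mode)
            qplogs, aex = sd.sp["QPlogS"], sd.aex
        cls = assign_class(qplogs, aex)
        per_group.setdefault(rec.group, Counter())[cls] += 1
        if rec.group == "APR":
            if cls == POSITIVE_CLASS:
                tp += 1
            else:
                fn += 1
        elif rec.group == "CONTROL":
            if cls == POSITIVE_CLASS:
                fp += 1
            else:
                tn += 1
    return per_group, ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else math.nan


def cooper_statistics(c: ConfusionCounts) -> CooperStats:
    """Compute the nine Cooper statistics from confusion counts.

    Any statistic whose denominator is zero is reported as NaN; the
    others are still computed.
    """
    if c.n == 0:
        raise ValueError("empty confusion table")
    return CooperStats(
        sn=_ratio(c.tp, c.tp + c.fn),
        sp=_ratio(c.tn, c.tn + c.fp),
        ac=_ratio(c.tp + c.tn, c.n),
        er=_ratio(c.n - (c.tp + c.tn), c.n),
        pp=_ratio(c.tp, c.tp + c.fp),
        np=_ratio(c.tn, c.tn + c.fn),
        fp_oc=_ratio(c.fp, c.fp + c.tn),
        fn_uc=_ratio(c.fn, c.fn + c.tp),
        pas=_ratio(c.tn, c.tn + c.fp),
    )


def scan_protein(
    sequence: str,
    tables: dict[str, ResidueParamTable],
    window: int = 5,
    denominator_mode: str = DISTINCT,
    parent_id: str = "protein",
) -> list[WindowCall]:
    """Score every length-``window`` substring of a protein.

    Windows containing residues outside the canonical 20-letter alphabet,
    or residues absent from the parameter tables, are reported with class
    U and no descriptors; so are windows whose AEx is undefined. Class-D
    windows are the aggregation-prone candidates.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    sequence = sequence.upper()
    if len(sequence) < window:
        log.warning(
            "%s: sequence length %d < window %d; nothing to scan",
            parent_id, len(sequence), window,
        )
        return []
    calls: list[WindowCall] = []
    n_skipped = 0
    for start in range(1, len(sequence) - window + 2):
        sub = sequence[start - 1 : start - 1 + window]
        if set(sub) - set(CANONICAL_RESIDUES):
            calls.append(WindowCall(parent_id, start, start + window - 1, sub, None, UNCLASSIFIABLE))
            n_skipped += 1
            continue
        try:
            sd = compute_descriptors(sub, tables, denominator_mode)
        except KeyError:
            calls.append(WindowCall(parent_id, start, start + window - 1, sub, None, UNCLASSIFIABLE))
            n_skipped += 1
            continue
        if not sd.aex_defined:
            cls = UNCLASSIFIABLE
        else:
            cls = assign_class(sd.sp["QPlogS"], sd.aex)
        calls.append(WindowCall(parent_id, start, start + window - 1, sub, sd, cls))
    if n_skipped:
        log.warning("%s: %d window(s) skipped (non-scorable residues)", parent_id, n_skipped)
    return calls


def window_calls_tsv(calls: list[WindowCall]) -> str:
    """Render scanner output as the tab-separated report format."""
    header = (
        "seq_id\tstart\tend\twindow\t" + "\t".join(DESCRIPTORS) + "\tAEx\tclass\tapr_flag"
    )
    lines = [header]
    for c in calls:
        if c.descriptors is None:
            vals = ["NA"] * (len(DESCRIPTORS) + 1)
        else:
            vals = [f"{c.descriptors.sp[d]:.4f}" for d in DESCRIPTORS]
            vals.append("NA" if not c.descriptors.aex_defined else f"{c.descriptors.aex:.4f}")
        lines.append(
            f"{c.parent_id}\t{c.start}\t{c.end}\t{c.window_sequence}\t"
            + "\t".join(vals)
            + f"\t{c.assigned_class}\t{int(c.is_apr_candidate)}"
        )
    return "\n".join(lines) + "\n"
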