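"""One-shot reproduction report for the packaged reference dataset.

Recomputes, from the packaged table alone: the per-row AEx consistency
check, the quadrant class counts per group, the Cooper validation
statistics of the APR-vs-control confusion table, group summary
statistics per descriptor, and the two Mann-Whitney comparisons (AEx and
QPlogS, APR vs control). Each block is written as a TSV; internal checks
against the published counts are collected and reported.
"""

from __future__ import annotations

import math
from collections import Counter
from pathlib import Path

from .classify import classify_dataset, cooper_statistics
from .descriptors import DESCRIPTORS, compute_aex, round_half_away
from .reference_data import SequenceRecord, load_reference_table
from .stats import mann_whitney_z, summary

#: Published reference counts the report re-checks itself against.
EXPECTED_CLASS_COUNTS = {
    "APR": {"A": 0, "B": 9, "C": 8, "D": 67},
    "CONTROL": {"A": 2, "B": 22, "C": 17, "D": 1},
}
EXPECTED_CONFUSION = {"tp": 67, "fn": 17, "tn": 41, "fp": 1}
EXPECTED_COOPER = {
    "sn": 79.76, "sp": 97.62, "ac": 85.71, "er": 14.29,
    "pp": 98.53, "np": 70.69, "fp_oc": 2.38, "fn_uc": 20.24,
}
#: Id of the one row whose printed AEx does not follow from its own
#: descriptor columns (VVSVL; printed 0.00, recomputed ~ -2.46).
ANOMALOUS_ROW_ID = 129
AEX_TOLERANCE = 0.02


def recomputed_aex(rec: SequenceRecord) -> float:
    return compute_aex(rec.am, rec.ac, rec.rot, rec.ip, rec.qpcaco, rec.non)


def aex_consistency(records: list[SequenceRecord]) -> list[dict]:
    """Per-row comparison of recomputed vs printed AEx."""
    rows = []
    for rec in records:
        rec_aex = recomputed_aex(rec)
        delta = rec_aex - rec.aex_printed
        rows.append({
            "id": rec.id,
            "sequence": rec.sequence,
            "aex_printed": rec.aex_printed,
            "aex_recomputed": round_half_away(rec_aex, 4),
            "consistent": abs(delta) <= AEX_TOLERANCE,
        })
    return rows


def reproduce_reference_results(output_dir: str | Path) -> tuple[dict, list[str]]:
    """Run the full reproduction and write report TSVs into ``output_dir``.

    Returns the computed results plus a list of failed internal checks
    (empty on full success).
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = load_reference_table()
    failures: list[str] = []

    # (i) per-row AEx consistency
    aex_rows = aex_consistency(records)
    inconsistent = [r["id"] for r in aex_rows if not r["consistent"]]
    if inconsistent != [ANOMALOUS_ROW_ID]:
        failures.append(f"AEx inconsistencies at rows {inconsistent}, expected only {ANOMALOUS_ROW_ID}")
    _write_tsv(outdir / "aex_check.tsv",
               ["id", "sequence", "aex_printed", "aex_recomputed", "consistent"],
               aex_rows)

    # (ii) class counts and confusion table
    per_group, confusion = classify_dataset(records, use_printed=True)
    count_rows = []
    for group, expected in EXPECTED_CLASS_COUNTS.items():
        got = {cls: per_group[group].get(cls, 0) for cls in "ABCD"}
        if got != expected:
            failures.append(f"{group} class counts {got} != published {expected}")
        count_rows.append({"group": group, **got})
    treg = {cls: per_group.get("TREGITOPE", Counter()).get(cls, 0) for cls in "ABCD"}
    count_rows.append({"group": "TREGITOPE", **treg})
    _write_tsv(outdir / "class_counts.tsv", ["group", "A", "B", "C", "D"], count_rows)
    got_conf = {"tp": confusion.tp, "fn": confusion.fn, "tn": confusion.tn, "fp": confusion.fp}
    if got_conf != EXPECTED_CONFUSION:
        failures.append(f"confusion table {got_conf} != published {EXPECTED_CONFUSION}")

    # (iii) Cooper statistics
    cooper = cooper_statistics(confusion)
    cooper_rows = [{"statistic": k, "percent": round_half_away(getattr(cooper, k), 2)}
                   for k in ("sn", "sp", "ac", "er", "pp", "np", "fp_oc", "fn_uc", "pas")]
    for k, want in EXPECTED_COOPER.items():
        got = round_half_away(getattr(cooper, k), 2)
        if not math.isclose(got, want, abs_tol=0.005):
            failures.append(f"Cooper {k}: {got} != published {want}")
    _write_tsv(outdir / "cooper.tsv", ["statistic", "percent"], cooper_rows)

    # (iv) group summaries per descriptor (plus AEx)
    summary_rows = []
    for group in ("APR", "TREGITOPE", "CONTROL"):
        members = [r for r in records if r.group == group]
        for desc in DESCRIPTORS + ("AEx",):
            vals = ([r.aex_printed for r in members] if desc == "AEx"
                    else [r.descriptor_values()[desc] for r in members])
            s = summary(vals)
            summary_rows.append({
                "group": group, "descriptor": desc, "n": s.n,
                "M": round_half_away(s.m, 4), "SD": round_half_away(s.sd, 4),
                "SE": round_half_away(s.se, 4),
                "CI_low": round_half_away(s.ci_low, 4),
                "CI_high": round_half_away(s.ci_high, 4),
            })
    _write_tsv(outdir / "group_summaries.tsv",
               ["group", "descriptor", "n", "M", "SD", "SE", "CI_low", "CI_high"],
               summary_rows)

    # (v) Mann-Whitney comparisons, APR vs control
    apr = [r for r in records if r.group == "APR"]
    cs = [r for r in records if r.group == "CONTROL"]
    rank_rows = []
    ranktests = {}
    for label, get in (("AEx", lambda r: r.aex_printed), ("QPlogS", lambda r: r.qplogs)):
        res = mann_whitney_z([get(r) for r in apr], [get(r) for r in cs])
        ranktests[label] = res
        rank_rows.append({
            "comparison": f"{label} APR vs CS", "U": res.u,
            "Zc": round_half_away(res.zc, 3),
            "p_two_sided": f"{res.p_two_sided:.3g}",
        })
    _write_tsv(outdir / "rank_tests.tsv", ["comparison", "U", "Zc", "p_two_sided"], rank_rows)

    results = {
        "aex_rows": aex_rows,
        "per_group": per_group,
        "confusion": confusion,
        "cooper": cooper,
        "summaries": summary_rows,
        "rank_tests": ranktests,
    }
    return results, failures


def _write_tsv(path: Path, columns: list[str], rows: list[dict]) -> None:
    lines = ["\t".join(columns)]
    for row in rows:
        lines.append("\t".join(str(row[c]) for c in columns))
    path.write_text("\n".join(lines) + "\n")
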